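"""File formats, run configuration, and the report bundle.

Cohorts travel as one wide CSV (item columns named by the design's item
ids, time columns ``time_p1..time_pK``, the demographic columns, a
``careless`` label column and an optional ``careless_style`` column),
with the scale design in a YAML sidecar. CSVs written by the pipeline
carry ``#``-prefixed metadata lines (config hash, seed) and are read back
with ``comment='#'``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .indices import IndexConfig
from .screening import GBMConfig, ValidationPlan
from .synthetic import ScaleDesign, SurveyCohort, TimingModel

logger = logging.getLogger(__name__)

DEMOGRAPHIC_COLUMNS = ("age", "gender", "occupation", "education")


# ---------------------------------------------------------------------------
# design sidecar
# ---------------------------------------------------------------------------

def save_design_yaml(design: ScaleDesign, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(design.to_dict(), sort_keys=False))


def load_design_yaml(path: str | Path) -> ScaleDesign:
    return ScaleDesign.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

def _metadata_header(metadata: Mapping[str, Any] | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in metadata.items())


def write_table_csv(frame: pd.DataFrame, path: str | Path,
                    metadata: Mapping[str, Any] | None = None,
                    index: bool = False) -> None:
    """CSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_header(metadata))
        frame.to_csv(fh, index=index)


def read_table_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so write-then-read preserves floats bit-exactly
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_cohort_csv(cohort: SurveyCohort, path: str | Path,
                     metadata: Mapping[str, Any] | None = None) -> None:
    write_table_csv(cohort.to_wide_frame(), path, metadata=metadata)


def load_survey_csv(path: str | Path, design: ScaleDesign) -> SurveyCohort:
    """Typed cohort from a wide CSV. Unknown columns are preserved as
    pass-through; reverse-coded items are identified by the ``_r`` suffix
    convention in the design's item ids."""
    df = read_table_csv(path)
    missing = [c for c in design.item_ids if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing item column(s): "
                         f"{missing}")
    resp = df[list(design.item_ids)]
    bad = resp.apply(lambda s: ~(s.astype(float) % 1 == 0)
                     | (s < design.likert_min) | (s > design.likert_max))
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], resp.columns[cols[0]]
        raise ValueError(f"non-integer or out-of-range response at row {r}, "
                         f"column {c!r}: {resp.iloc[r][c]!r}")
    resp = resp.astype(int)

    time_cols = [f"time_p{k}" for k in range(1, design.n_scales + 1)]
    missing_t = [c for c in time_cols if c not in df.columns]
    if missing_t:
        raise ValueError(f"cohort file missing time column(s): {missing_t}")
    times = df[time_cols].astype(float)

    demo_cols = [c for c in DEMOGRAPHIC_COLUMNS if c in df.columns]
    demo = df[demo_cols].copy()

    if "careless" in df.columns:
        labels = df["careless"].to_numpy(dtype=int)
    else:
        labels = np.zeros(len(df), dtype=int)
    if "careless_style" in df.columns:
        style = df["careless_style"].astype("object")
        style = style.where(style.notna(), None)
    else:
        style = pd.Series([None] * len(df), dtype="object")
        style[labels == 1] = "unknown"
    style.name = "careless_style"

    known = set(design.item_ids) | set(time_cols) | set(demo_cols) \
        | {"careless", "careless_style"}
    extra_cols = [c for c in df.columns if c not in known]
    extra = df[extra_cols].copy() if extra_cols else None

    return SurveyCohort(responses=resp, times=times, demographics=demo,
                        labels=labels, careless_style=style, design=design,
                        extra=extra)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from a YAML file."""

    outdir: str = "careless_run"
    seed: int = 1
    n_regular: int = 361
    n_careless: int = 244
    timing: TimingModel = field(default_factory=TimingModel)
    plan: ValidationPlan = field(default_factory=ValidationPlan)
    gbm: GBMConfig = field(default_factory=GBMConfig)
    index: IndexConfig = field(default_factory=IndexConfig)
    scenarios: tuple[str, ...] = ("resp", "rt", "dem", "careless",
                                  "resp_dem", "rt_dem", "resp_rt",
                                  "all", "all_extracted")
    explain_samples: int = 200
    ledger_top_k: int = 5
    ledger_min_abs: float = 0.01

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = list(self.scenarios)
        return d

    def scaled_down(self) -> "RunConfig":
        """Shrunk repeats/grid/samples for quick runs (--scale-down)."""
        cfg = RunConfig(**{**self.to_dict(),
                           "timing": self.timing,
                           "plan": ValidationPlan(
                               n_repeats=min(self.plan.n_repeats, 5),
                               train_size=self.plan.train_size,
                               test_size=self.plan.test_size,
                               inner_folds=min(self.plan.inner_folds, 3),
                               base_seed=self.plan.base_seed,
                               stratify=self.plan.stratify),
                           "gbm": GBMConfig.compact(seed=self.gbm.seed),
                           "index": self.index,
                           "explain_samples": min(self.explain_samples, 60),
                           "scenarios": ("rt", "dem", "all", "all_extracted")})
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def metadata(self) -> dict[str, Any]:
        return {"config_hash": self.config_hash(), "seed": self.seed}


def load_config(path: str | Path | None) -> RunConfig:
    """RunConfig from YAML; absent keys fall back to defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw: dict[str, Any] = {}
    for key in ("outdir", "seed", "n_regular", "n_careless",
                "explain_samples", "ledger_top_k", "ledger_min_abs"):
        if key in raw:
            kw[key] = raw[key]
    if "scenarios" in raw:
        kw["scenarios"] = tuple(raw["scenarios"])
    if "timing" in raw:
        kw["timing"] = TimingModel(**raw["timing"])
    if "plan" in raw:
        kw["plan"] = ValidationPlan(**raw["plan"])
    if "gbm" in raw:
        g = {k: tuple(v) if isinstance(v, list) else v
             for k, v in raw["gbm"].items()}
        kw["gbm"] = GBMConfig(**g)
    if "index" in raw:
        kw["index"] = IndexConfig(**raw["index"])
    return RunConfig(**kw)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

REPORT_SECTIONS = {
    "benchmark_summary": "benchmark_summary.csv",
    "benchmark_repeats": "benchmark_repeats.csv",
    "ledger": "ledger.csv",
    "ledger_text": "ledger.txt",
    "indices": "indices.csv",
    "cohort": "cohort.csv",
}


def run_report(outdir: str | Path, config: RunConfig) -> Path:
    """Assemble the report bundle: manifest + plain-text summary.

    Missing stage outputs are marked, not fatal.
    """
    outdir = Path(outdir)
    report_dir = outdir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)

    import careless_screen
    import sklearn

    present: dict[str, bool] = {}
    lines = ["careless-screen run report", "=" * 27, ""]
    for section, fname in REPORT_SECTIONS.items():
        path = outdir / fname
        present[section] = path.exists()
        lines.append(f"[{'ok' if present[section] else 'MISSING'}] "
                     f"{section}: {fname}")
    if present["benchmark_summary"]:
        summ = read_table_csv(outdir / "benchmark_summary.csv")
        lines += ["", "Balanced accuracy by scenario (mean +/- sd):"]
        for _, r in summ.iterrows():
            lines.append(f"  {r['scenario']:<14} {r['mean']:.3f} "
                         f"+/- {0.0 if pd.isna(r['sd']) else r['sd']:.3f} "
                         f"({int(r['n_repeats'])} repeats)")
    if present["ledger_text"]:
        lines += ["", "Variable appropriateness ledger:",
                  (outdir / "ledger.txt").read_text().rstrip()]

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "sections": present,
        "versions": {
            "careless_screen": careless_screen.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    (report_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    (report_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return report_dir
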