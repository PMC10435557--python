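"""Careless-responding indices computed from a Likert response matrix.

Implements the classical survey data-quality screens: longstring (maximum
and average run of identical consecutive answers), intra-individual
response variability (IRV, total and per section), psychometric synonym
and antonym scores (within-person correlation over strongly correlated
item pairs), Mahalanobis distance from the sample mean vector, and the
even-odd consistency index (within-person correlation between even- and
odd-half scale means across subscales).

Undefined scores (e.g. a zero-variance respondent's within-person
correlation) are reported as NaN, never as 0 — a correlation of 0 is a
meaningful value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import ScaleDesign, SurveyCohort

logger = logging.getLogger(__name__)

#: Default inter-item correlation cutoffs for pair selection.
SYNONYM_THRESHOLD = 0.60
ANTONYM_THRESHOLD = -0.60

BASE_INDEX_COLUMNS = ("res_psycsyn", "res_psychant", "str", "avgstr",
                      "res_mahad", "res_evenodd", "irvTotal")
DERIVED_INDEX_COLUMNS = ("irvDiff", "longDiff")


@dataclass(frozen=True)
class ItemPairSet:
    """Item pairs selected by an inter-item correlation cutoff."""

    mode: str                              # "synonym" or "antonym"
    pairs: tuple[tuple[str, str], ...]
    threshold: float

    def __post_init__(self) -> None:
        if self.mode not in ("synonym", "antonym"):
            raise ValueError(f"unknown pair mode {self.mode!r}")
        if any(a == b for a, b in self.pairs):
            raise ValueError("self-pairs are not allowed")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class IndexConfig:
    """Options for building the index table."""

    synonym_threshold: float = SYNONYM_THRESHOLD
    antonym_threshold: float = ANTONYM_THRESHOLD
    spearman_brown: bool = False
    include_derived: bool = False   # irvDiff / longDiff


# ---------------------------------------------------------------------------
# per-respondent primitives
# ---------------------------------------------------------------------------

def run_lengths(row: Sequence[int]) -> np.ndarray:
    """Lengths of maximal runs of equal consecutive values."""
    arr = np.asarray(row)
    if arr.size == 0:
        raise ValueError("row must be non-empty")
    change = np.flatnonzero(arr[1:] != arr[:-1])
    bounds = np.concatenate(([0], change + 1, [arr.size]))
    return np.diff(bounds)


def longstring_stats(row: Sequence[int]) -> tuple[int, float]:
    """(longest run, mean run length) of identical consecutive responses."""
    runs = run_lengths(row)
    return int(runs.max()), float(runs.mean())


def irv(row: Sequence[float], item_subset: slice | Sequence[int] | None = None
        ) -> float:
    """Sample standard deviation of a respondent's responses over a subset."""
    arr = np.asarray(row, dtype=float)
    if item_subset is not None:
        arr = arr[item_subset]
    if arr.size < 2:
        raise ValueError("irv needs at least 2 items")
    return float(np.std(arr, ddof=1))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def find_item_pairs(matrix: pd.DataFrame, threshold: float,
                    mode: str = "synonym") -> ItemPairSet:
    """All unordered item pairs whose inter-item Pearson correlation
    passes the cutoff (``>= threshold`` for synonyms with threshold in
    (0, 1]; ``<= threshold`` for antonyms with threshold in [-1, 0)).

    Constant item columns have undefined correlations and are excluded
    with a logged warning.
    """
    if mode == "synonym" and not 0.0 < threshold <= 1.0:
        raise ValueError("synonym threshold must be in (0, 1]")
    if mode == "antonym" and not -1.0 <= threshold < 0.0:
        raise ValueError("antonym threshold must be in [-1, 0)")
    if len(matrix) < 3:
        raise ValueError("need at least 3 respondents to select pairs")

    values = matrix.to_numpy(dtype=float)
    keep = np.ptp(values, axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(matrix.columns, keep) if not k]
        logger.warning("excluding %d constant item column(s) from pair "
                       "selection: %s", len(dropped), dropped)
    cols = [c for c, k in zip(matrix.columns, keep) if k]
    corr = np.corrcoef(values[:, keep], rowvar=False)
    pairs = []
    for i, j in combinations(range(len(cols)), 2):
        r = corr[i, j]
        if (mode == "synonym" and r >= threshold) or \
           (mode == "antonym" and r <= threshold):
            pairs.append((cols[i], cols[j]))
    return ItemPairSet(mode=mode, pairs=tuple(pairs), threshold=threshold)


def psych_score(row: pd.Series, pairs: ItemPairSet) -> float:
    """Within-person correlation between first- and second-pair-member
    responses; NaN (flagged) with fewer than 2 pairs or a constant vector."""
    if len(pairs) < 2:
        return float("nan")
    x = np.array([row[a] for a, _ in pairs.pairs], dtype=float)
    y = np.array([row[b] for _, b in pairs.pairs], dtype=float)
    return _pearson(x, y)


def mahalanobis_distances(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Distance of each respondent's response vector from the vector of
    sample means under the sample covariance. A pseudo-inverse is used
    (with a logged flag) when the covariance is singular, e.g. p > n."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 respondents")
    centered = X - X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    rank = np.linalg.matrix_rank(cov)
    if rank < cov.shape[0]:
        logger.warning("singular covariance (rank %d < %d); using "
                       "pseudo-inverse", rank, cov.shape[0])
    # pinv coincides with the inverse for full-rank covariances and
    # projects out null-space directions otherwise
    inv = np.linalg.pinv(cov, hermitian=True)
    d2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
    return np.sqrt(np.clip(d2, 0.0, None))


def even_odd(matrix: pd.DataFrame, design: ScaleDesign,
             spearman_brown: bool = False) -> np.ndarray:
    """Even-odd consistency: per respondent, the correlation across scales
    between even-position and odd-position half-scale means.

    With only two scales the correlation is degenerate (two points force
    |r| = 1); a warning is logged and results should be read as flags.
    Optional Spearman-Brown step-up ``2r / (1 + r)``.
    """
    if design.n_scales < 2:
        raise ValueError("need at least 2 scales")
    if design.items_per_scale < 2:
        raise ValueError("every scale needs at least 2 items")
    if design.n_scales == 2:
        logger.warning("even-odd with 2 scales is degenerate: two points "
                       "force |r| = 1 or undefined")
    X = matrix.to_numpy(dtype=float)
    odd_means = np.empty((X.shape[0], design.n_scales))
    even_means = np.empty_like(odd_means)
    for s, sl in enumerate(design.section_slices()):
        block = X[:, sl]
        odd_means[:, s] = block[:, 0::2].mean(axis=1)   # positions 1,3,5,...
        even_means[:, s] = block[:, 1::2].mean(axis=1)  # positions 2,4,6,...
    out = np.array([_pearson(o, e) for o, e in zip(odd_means, even_means)])
    if spearman_brown:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(out == -1.0, np.nan, 2.0 * out / (1.0 + out))
    return out


# ---------------------------------------------------------------------------
# the index table
# ---------------------------------------------------------------------------

def compute_index_table(cohort: SurveyCohort,
                        config: IndexConfig | None = None) -> pd.DataFrame:
    """Per-respondent index table (the "Careless" variable block).

    Default 13 columns: res_psycsyn, res_psychant, str, avgstr, res_mahad,
    res_evenodd, irvTotal, irv1..irv6. With ``include_derived``, appends
    irvDiff (IRV of last section minus first) and longDiff (longstring of
    last section minus first). Undefined scores propagate as NaN; per-column
    NaN counts are logged.
    """
    config = config or IndexConfig()
    design = cohort.design
    resp = cohort.responses
    X = resp.to_numpy()

    syn = find_item_pairs(resp, config.synonym_threshold, "synonym")
    ant = find_item_pairs(resp, config.antonym_threshold, "antonym")
    if len(syn) < 2:
        logger.warning("only %d synonym pair(s) found; res_psycsyn undefined",
                       len(syn))
    if len(ant) < 2:
        logger.warning("only %d antonym pair(s) found; res_psychant undefined",
                       len(ant))

    n = cohort.n
    table = pd.DataFrame(index=resp.index)
    table["res_psycsyn"] = [psych_score(resp.iloc[i], syn) for i in range(n)]
    table["res_psychant"] = [psych_score(resp.iloc[i], ant) for i in range(n)]
    runs = [longstring_stats(X[i]) for i in range(n)]
    table["str"] = [r[0] for r in runs]
    table["avgstr"] = [r[1] for r in runs]
    table["res_mahad"] = mahalanobis_distances(X)
    table["res_evenodd"] = even_odd(resp, design,
                                    spearman_brown=config.spearman_brown)
    table["irvTotal"] = np.std(X, axis=1, ddof=1)
    slices = design.section_slices()
    for k, sl in enumerate(slices, start=1):
        table[f"irv{k}"] = np.std(X[:, sl], axis=1, ddof=1)

    if config.include_derived:
        first, last = slices[0], slices[-1]
        table["irvDiff"] = table[f"irv{design.n_scales}"] - table["irv1"]
        table["longDiff"] = np.array(
            [longstring_stats(X[i, last])[0] - longstring_stats(X[i, first])[0]
             for i in range(n)], dtype=float)

    nan_counts = table.isna().sum()
    for col, cnt in nan_counts[nan_counts > 0].items():
        logger.info("index column %s: %d undefined value(s)", col, cnt)
    return table


def literature_cutoff_flags(table: pd.DataFrame,
                            longstring_cutoff: int = 7,
                            evenodd_cutoff: float = 0.3) -> pd.DataFrame:
    """Optional reporting utility: conventional literature cutoffs
    (longstring > 7; even-odd consistency < 0.3). Not part of the
    pipeline's label logic."""
    return pd.DataFrame({
        "flag_longstring": table["str"] > longstring_cutoff,
        "flag_evenodd": table["res_evenodd"] < evenodd_cutoff,
    }, index=table.index)
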