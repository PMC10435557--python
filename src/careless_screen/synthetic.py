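"""Synthetic survey cohorts with regular and careless respondents.

Generates Likert response matrices with the structure of a multi-scale
personality questionnaire (by default 6 scales x 10 items on a 1-5 range,
some items stored reverse-coded), per-section response times, a small
demographic block, and binary careless/regular labels.

Regular respondents answer from one latent trait per scale; careless
respondents follow one of three canonical inattentive styles:

* ``random`` -- uniform over the response categories,
* ``midpoint`` -- inflated probability on the middle category,
* ``pattern`` -- a fixed response pattern tiled across the questionnaire
  (the default is straightlining, i.e. a constant pattern of length 1).

Section response times are log-normal with group means of 57755.95 ms
(regular) and 43271.06 ms (careless), so careless respondents are faster
on average, which is the timing signal the screening model can exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CARELESS_STYLES = ("random", "midpoint", "pattern")

#: Demographic category labels and sampling probabilities.
GENDER_LEVELS = ("female", "male", "diverse")
GENDER_PROBS = (0.667, 0.313, 0.020)
OCCUPATION_LEVELS = ("student", "manual_worker", "employee",
                     "self_employed", "retired", "other")
OCCUPATION_PROBS = (0.281, 0.028, 0.393, 0.050, 0.165, 0.083)
EDUCATION_LEVELS = ("primary", "secondary", "tertiary", "postgraduate")
EDUCATION_PROBS = (0.08, 0.45, 0.37, 0.10)

AGE_MEAN = 43.1
AGE_SD = 17.8
AGE_RANGE = (18.0, 90.0)


@dataclass(frozen=True)
class ScaleDesign:
    """Layout of the questionnaire: scales, items, response range.

    Items are ordered; sections (scales) partition them into consecutive
    blocks of ``items_per_scale``. Reverse-coded items carry a ``_r``
    suffix in their identifier and are stored flipped at generation time.
    """

    n_scales: int = 6
    items_per_scale: int = 10
    likert_min: int = 1
    likert_max: int = 5
    item_ids: tuple[str, ...] = ()
    reverse_coded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.likert_max <= self.likert_min:
            raise ValueError("Likert range must have positive width")
        if not self.item_ids:
            object.__setattr__(self, "item_ids", self._default_item_ids())
            object.__setattr__(
                self, "reverse_coded",
                frozenset(i for i in self.item_ids if i.endswith("_r")))
        if len(self.item_ids) != self.n_scales * self.items_per_scale:
            raise ValueError(
                f"expected {self.n_scales * self.items_per_scale} item ids, "
                f"got {len(self.item_ids)}")
        unknown = set(self.reverse_coded) - set(self.item_ids)
        if unknown:
            raise ValueError(f"reverse_coded ids not in item_ids: {sorted(unknown)}")

    def _default_item_ids(self) -> tuple[str, ...]:
        # positions 3 and 8 within each scale are reverse-coded by default
        ids = []
        for k in range(1, self.n_scales * self.items_per_scale + 1):
            pos = (k - 1) % self.items_per_scale + 1
            suffix = "_r" if pos in (3, 8) else ""
            ids.append(f"IT01_{k:02d}{suffix}")
        return tuple(ids)

    @property
    def n_items(self) -> int:
        return self.n_scales * self.items_per_scale

    @property
    def midpoint(self) -> float:
        return (self.likert_min + self.likert_max) / 2.0

    @property
    def middle_category(self) -> int:
        """The integer middle category; raises if the range has none."""
        mid = self.likert_min + self.likert_max
        if mid % 2 != 0:
            raise ValueError(
                "even-width Likert range has no middle category; "
                "configure one explicitly")
        return mid // 2

    def section_of(self, item_id: str) -> int:
        """1-based section index of an item."""
        return self.item_ids.index(item_id) // self.items_per_scale + 1

    def section_slices(self) -> list[slice]:
        return [slice(s * self.items_per_scale, (s + 1) * self.items_per_scale)
                for s in range(self.n_scales)]

    def reverse_mask(self) -> np.ndarray:
        return np.array([i in self.reverse_coded for i in self.item_ids])

    def to_dict(self) -> dict:
        return {
            "n_scales": self.n_scales,
            "items_per_scale": self.items_per_scale,
            "likert_min": self.likert_min,
            "likert_max": self.likert_max,
            "item_ids": list(self.item_ids),
            "reverse_coded": sorted(self.reverse_coded),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScaleDesign":
        return cls(
            n_scales=int(d["n_scales"]),
            items_per_scale=int(d["items_per_scale"]),
            likert_min=int(d["likert_min"]),
            likert_max=int(d["likert_max"]),
            item_ids=tuple(d["item_ids"]),
            reverse_coded=frozenset(d["reverse_coded"]),
        )


@dataclass(frozen=True)
class CarelessSpec:
    """One careless answering style and its parameters."""

    style: str = "random"
    pattern: tuple[int, ...] = ()
    midpoint_prob: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.style not in CARELESS_STYLES:
            raise ValueError(f"unknown careless style {self.style!r}")
        if not 0.0 < self.midpoint_prob <= 1.0:
            raise ValueError("midpoint_prob must be in (0, 1]")

    def validate_for(self, design: ScaleDesign) -> None:
        if self.style == "pattern":
            if not self.pattern:
                raise ValueError("pattern style requires a non-empty pattern")
            bad = [v for v in self.pattern
                   if not design.likert_min <= v <= design.likert_max]
            if bad:
                raise ValueError(f"pattern values outside Likert range: {bad}")
        if self.style == "midpoint":
            design.middle_category  # raises for even-width ranges


@dataclass(frozen=True)
class TimingModel:
    """Log-normal section-time model, parameterized by group means (ms).

    Defaults match the study conditions: regular respondents average
    57755.95 ms per section, careless respondents 43271.06 ms.
    """

    regular_section_mean: float = 57755.95
    careless_section_mean: float = 43271.06
    dispersion: float = 0.35  # coefficient of variation
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.regular_section_mean <= 0 or self.careless_section_mean <= 0:
            raise ValueError("section-time means must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def lognormal_params(self, mean: float) -> tuple[float, float]:
        """(mu, sigma) of the log so that E[T] = mean, CV = dispersion."""
        sigma2 = np.log1p(self.dispersion ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return mu, float(np.sqrt(sigma2))


@dataclass
class SurveyCohort:
    """A labelled survey cohort: the unit every pipeline stage consumes."""

    responses: pd.DataFrame          # respondents x items (ints)
    times: pd.DataFrame              # respondents x sections (ms)
    demographics: pd.DataFrame       # age, gender, occupation, education
    labels: np.ndarray               # 1 = careless, 0 = regular
    careless_style: pd.Series        # style name, NA for regular
    design: ScaleDesign
    extra: pd.DataFrame | None = None  # pass-through columns

    def __post_init__(self) -> None:
        n = len(self.responses)
        for name, block in (("times", self.times),
                            ("demographics", self.demographics)):
            if len(block) != n:
                raise ValueError(f"{name} row count differs from responses")
        if len(self.labels) != n or len(self.careless_style) != n:
            raise ValueError("labels/styles row count differs from responses")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        vals = self.responses.to_numpy()
        if (vals < self.design.likert_min).any() or (vals > self.design.likert_max).any():
            raise ValueError("responses outside the configured Likert range")
        has_style = self.careless_style.notna().to_numpy()
        if not np.array_equal(has_style, self.labels == 1):
            raise ValueError("careless_style must be present iff label == 1")

    @property
    def n(self) -> int:
        return len(self.responses)

    def to_wide_frame(self) -> pd.DataFrame:
        """Single wide table: items, times, demographics, label, style."""
        parts = [self.responses, self.times, self.demographics,
                 pd.DataFrame({"careless": self.labels,
                               "careless_style": self.careless_style})]
        if self.extra is not None and not self.extra.empty:
            parts.append(self.extra)
        out = pd.concat(parts, axis=1)
        out.index = self.responses.index
        return out

    def equals(self, other: "SurveyCohort") -> bool:
        return (self.to_wide_frame().equals(other.to_wide_frame())
                and self.design == other.design)


# ---------------------------------------------------------------------------
# response simulation
# ---------------------------------------------------------------------------

def simulate_regular(design: ScaleDesign, n: int, loading: float = 1.0,
                     noise_sd: float = 0.8,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate attentive respondents from a one-factor-per-scale model.

    Each respondent draws a standard-normal latent trait per scale; an
    item's response is ``midpoint + loading * trait + noise`` rounded and
    clipped to the Likert range. Reverse-coded items are stored flipped
    (``likert_min + likert_max - value``), emulating raw storage where
    some responses arrive reversed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    traits = rng.normal(size=(n, design.n_scales))
    noise = rng.normal(scale=noise_sd, size=(n, design.n_items)) if noise_sd > 0 \
        else np.zeros((n, design.n_items))
    per_item_trait = np.repeat(traits, design.items_per_scale, axis=1)
    raw = design.midpoint + loading * per_item_trait + noise
    resp = np.clip(np.rint(raw), design.likert_min, design.likert_max).astype(int)
    flip = design.reverse_mask()
    resp[:, flip] = design.likert_min + design.likert_max - resp[:, flip]
    return resp


def simulate_careless(design: ScaleDesign, n: int, spec: CarelessSpec,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate one block of careless respondents in the given style."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate_for(design)
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    p = design.n_items
    if spec.style == "random":
        return rng.integers(design.likert_min, design.likert_max + 1,
                            size=(n, p))
    if spec.style == "midpoint":
        cats = np.arange(design.likert_min, design.likert_max + 1)
        mid = design.middle_category
        probs = np.full(len(cats), (1.0 - spec.midpoint_prob) / (len(cats) - 1))
        probs[cats == mid] = spec.midpoint_prob
        return rng.choice(cats, size=(n, p), p=probs)
    # pattern: tile across all items, identical for every respondent
    tiled = np.tile(np.asarray(spec.pattern, dtype=int),
                    int(np.ceil(p / len(spec.pattern))))[:p]
    return np.tile(tiled, (n, 1))


def simulate_times_and_demographics(
        labels: np.ndarray, timing: TimingModel, n_sections: int = 6,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Section times (log-normal, group mean set by label) and demographics."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(
        seed if seed is not None else timing.seed)
    n = labels.size

    times = np.empty((n, n_sections))
    for lab, mean in ((0, timing.regular_section_mean),
                      (1, timing.careless_section_mean)):
        mask = labels == lab
        if mask.any():
            mu, sigma = timing.lognormal_params(mean)
            times[mask] = rng.lognormal(mu, sigma, size=(mask.sum(), n_sections))
    times_df = pd.DataFrame(
        times, columns=[f"time_p{k}" for k in range(1, n_sections + 1)])

    lo, hi = AGE_RANGE
    a, b = (lo - AGE_MEAN) / AGE_SD, (hi - AGE_MEAN) / AGE_SD
    ages = stats.truncnorm.rvs(a, b, loc=AGE_MEAN, scale=AGE_SD,
                               size=n, random_state=rng)
    demo = pd.DataFrame({
        "age": np.round(ages, 1),
        "gender": rng.choice(GENDER_LEVELS, size=n, p=GENDER_PROBS),
        "occupation": rng.choice(OCCUPATION_LEVELS, size=n, p=OCCUPATION_PROBS),
        "education": rng.choice(EDUCATION_LEVELS, size=n, p=EDUCATION_PROBS),
    })
    return times_df, demo


def _allocate(total: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of `total` across styles."""
    keys = list(proportions)
    quotas = np.array([proportions[k] * total for k in keys])
    base = np.floor(quotas).astype(int)
    rest = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for i in order[:rest]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def assemble_cohort(n_regular: int = 361, n_careless: int = 244,
                    style_mix: Mapping[str, float] | None = None,
                    design: ScaleDesign | None = None,
                    timing: TimingModel | None = None,
                    seed: int = 0,
                    loading: float = 1.0, noise_sd: float = 0.8,
                    careless_specs: Mapping[str, CarelessSpec] | None = None,
                    ) -> SurveyCohort:
    """Assemble a full labelled cohort (default 361 regular + 244 careless).

    ``style_mix`` gives the proportion of careless respondents per style
    (default: uniform over random/midpoint/pattern, realized by
    largest-remainder rounding). All randomness flows from ``seed``.
    """
    if n_regular < 0 or n_careless < 0:
        raise ValueError("counts must be non-negative")
    if n_regular == 0 and n_careless == 0:
        raise ValueError("cohort cannot be empty")
    design = design or ScaleDesign()
    timing = timing or TimingModel()
    style_mix = dict(style_mix) if style_mix else {s: 1 / 3 for s in CARELESS_STYLES}
    if abs(sum(style_mix.values()) - 1.0) > 1e-9:
        raise ValueError("style_mix proportions must sum to 1")
    if careless_specs is None:
        # default pattern style is straightlining (constant length-1 pattern)
        careless_specs = {
            "random": CarelessSpec(style="random"),
            "midpoint": CarelessSpec(style="midpoint", midpoint_prob=0.7),
            "pattern": CarelessSpec(style="pattern", pattern=(design.likert_min,)),
        }

    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    styles: list[str | None] = []
    if n_regular:
        blocks.append(simulate_regular(design, n_regular, loading=loading,
                                       noise_sd=noise_sd, rng=rng))
        styles += [None] * n_regular
    counts = _allocate(n_careless, style_mix) if n_careless else {}
    for style, cnt in counts.items():
        if cnt == 0:
            continue
        blocks.append(simulate_careless(design, cnt, careless_specs[style], rng=rng))
        styles += [style] * cnt

    responses = pd.DataFrame(np.vstack(blocks), columns=list(design.item_ids))
    labels = np.array([0] * n_regular + [1] * (len(styles) - n_regular))
    times, demo = simulate_times_and_demographics(
        labels, timing, n_sections=design.n_scales, rng=rng)
    style_series = pd.Series(styles, dtype="object", name="careless_style")
    logger.info("assembled cohort: n=%d (%d regular, %d careless: %s)",
                len(labels), n_regular, n_careless, counts)
    return SurveyCohort(responses=responses, times=times, demographics=demo,
                        labels=labels, careless_style=style_series,
                        design=design)
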