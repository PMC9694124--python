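"""Permutation analysis of cochlear-implant speech scores under two IIDR settings.

This module implements, end to end, the statistical pipeline of a paired
speech-audiometry comparison between two instantaneous input dynamic range
(IIDR) programs of a Cochlear Ltd. sound processor:

* the *default* IIDR maps acoustic levels between T-SPL 25 dB SPL and
  C-SPL 65 dB SPL onto the electrical dynamic range (width 40 dB);
* the *wide* IIDR raises C-SPL to 80 dB SPL (width 55 dB).

Eleven unilateral CI users, split by their self-selected program into a
``preCSPL65`` group (n=5) and a ``preCSPL80`` group (n=6), are tested with
both programs on recorded word lists (25 words, word scoring) and sentence
lists (15 sentences scored over 60 morphemes), in quiet and in
speech-weighted noise at +10 dB SNR, presented at 65 and 80 dB SPL.

Significance of a mean-score difference is assessed with a Monte Carlo
permutation test: item outcomes from the two conditions are pooled, a
pseudo-sample the size of one condition is drawn without replacement, the
mean difference of the split is recorded, and the p-value is the fraction of
100,000 such resamples whose difference is at least as extreme as the
observed one.

The file is organised in the order the analysis runs:

1. study constants and the bundled calibration preset (``figure3``),
2. domain types (IIDR settings, test conditions, response vectors, cohorts),
3. long-format CSV I/O,
4. the synthetic cohort generator,
5. the permutation engine (Monte Carlo + exact enumeration oracle),
6. the study pipeline (comparison matrix, report, significance patterns).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_IIDR",
    "WIDE_IIDR",
    "STUDY_GROUPS",
    "STUDY_GROUP_SIZES",
    "ITEMS_PER_MATERIAL",
    "FIGURE3_GROUP_MEANS",
    "EXPECTED_PATTERN_ALL_SUBJECTS",
    "SchemaError",
    "ValidationError",
    "CapacityError",
    "IIDRSetting",
    "TestCondition",
    "ItemResponseVector",
    "Cohort",
    "PermutationResult",
    "GeneratorConfig",
    "ComparisonSpec",
    "StudyReport",
    "iidr_width",
    "score_percent",
    "study_conditions",
    "read_responses",
    "write_responses",
    "generate_item_responses",
    "generate_cohort",
    "figure3_preset",
    "observed_mean_difference",
    "mc_permutation_test",
    "exact_permutation_test",
    "pool_cell",
    "default_comparison_matrix",
    "run_study",
    "summarize_means",
    "significance_pattern",
    "pattern_diff",
]

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# 1. Study constants and calibration preset
# ---------------------------------------------------------------------------

#: Items per list: word lists carry 25 words, sentence lists 15 sentences
#: scored over 60 morphemes; each binary item is one word / one morpheme.
ITEMS_PER_MATERIAL: Mapping[str, int] = {"word": 25, "sentence": 60}

#: Noise tests run at a fixed +10 dB signal-to-noise ratio.
STUDY_SNR_DB = 10

#: Presentation levels: conversational (65) and loud (80) speech, dB SPL.
STUDY_LEVELS_DB_SPL = (65, 80)

STUDY_GROUPS = ("preCSPL65", "preCSPL80")
STUDY_GROUP_SIZES: Mapping[str, int] = {"preCSPL65": 5, "preCSPL80": 6}

#: Default number of without-replacement resamples per test.
DEFAULT_N_RESAMPLES = 100_000

#: Significance thresholds the report flags (strict ``p < alpha``).
REPORT_ALPHAS = (0.05, 0.01)

# Per-group, per-cell mean percent-correct scores used to calibrate the
# synthetic cohort generator.  Keys: (group, material, environment,
# level_db_spl, iidr label).  These are the group-level condition means of
# the study; the preCSPL80 default-IIDR noise cells at 80 dB sit near the
# floor (0.7% words, 3.2% morphemes) and the two groups are completely
# separated in noise at 65 dB under the default program.
FIGURE3_GROUP_MEANS: Mapping[tuple[str, str, str, int, str], float] = {
    # preCSPL65, 65 dB SPL
    ("preCSPL65", "word", "quiet", 65, "default"): 92.8,
    ("preCSPL65", "word", "noise", 65, "default"): 70.4,
    ("preCSPL65", "sentence", "quiet", 65, "default"): 97.0,
    ("preCSPL65", "sentence", "noise", 65, "default"): 83.4,
    ("preCSPL65", "word", "quiet", 65, "wide"): 96.8,
    ("preCSPL65", "word", "noise", 65, "wide"): 77.6,
    ("preCSPL65", "sentence", "quiet", 65, "wide"): 94.8,
    ("preCSPL65", "sentence", "noise", 65, "wide"): 86.6,
    # preCSPL65, 80 dB SPL
    ("preCSPL65", "word", "quiet", 80, "default"): 84.0,
    ("preCSPL65", "word", "noise", 80, "default"): 29.6,
    ("preCSPL65", "sentence", "quiet", 80, "default"): 81.0,
    ("preCSPL65", "sentence", "noise", 80, "default"): 44.6,
    ("preCSPL65", "word", "quiet", 80, "wide"): 75.2,
    ("preCSPL65", "word", "noise", 80, "wide"): 44.8,
    ("preCSPL65", "sentence", "quiet", 80, "wide"): 91.2,
    ("preCSPL65", "sentence", "noise", 80, "wide"): 57.8,
    # preCSPL80, 65 dB SPL
    ("preCSPL80", "word", "quiet", 65, "default"): 67.3,
    ("preCSPL80", "word", "noise", 65, "default"): 16.6,
    ("preCSPL80", "sentence", "quiet", 65, "default"): 78.3,
    ("preCSPL80", "sentence", "noise", 65, "default"): 25.0,
    ("preCSPL80", "word", "quiet", 65, "wide"): 76.7,
    ("preCSPL80", "word", "noise", 65, "wide"): 40.7,
    ("preCSPL80", "sentence", "quiet", 65, "wide"): 83.5,
    ("preCSPL80", "sentence", "noise", 65, "wide"): 57.8,
    # preCSPL80, 80 dB SPL
    ("preCSPL80", "word", "quiet", 80, "default"): 46.0,
    ("preCSPL80", "word", "noise", 80, "default"): 0.7,
    ("preCSPL80", "sentence", "quiet", 80, "default"): 56.3,
    ("preCSPL80", "sentence", "noise", 80, "default"): 3.2,
    ("preCSPL80", "word", "quiet", 80, "wide"): 70.7,
    ("preCSPL80", "word", "noise", 80, "wide"): 31.3,
    ("preCSPL80", "sentence", "quiet", 80, "wide"): 75.5,
    ("preCSPL80", "sentence", "noise", 80, "wide"): 45.8,
}

#: Reported all-subjects significance pattern at alpha=0.05 for the
#: within-IIDR (default vs wide) comparisons: the wide program improved every
#: test except sentences in quiet at the conversational level.
#: Keys: (material, environment, level_db_spl).
EXPECTED_PATTERN_ALL_SUBJECTS: Mapping[tuple[str, str, int], bool] = {
    ("word", "quiet", 65): True,
    ("word", "noise", 65): True,
    ("sentence", "quiet", 65): False,
    ("sentence", "noise", 65): True,
    ("word", "quiet", 80): True,
    ("word", "noise", 80): True,
    ("sentence", "quiet", 80): True,
    ("sentence", "noise", 80): True,
}


class ValidationError(ValueError):
    """Input data violate a structural invariant of the study design."""


class SchemaError(ValidationError):
    """A response table is missing required columns."""


class CapacityError(RuntimeError):
    """Exact enumeration would exceed the configured assignment cap."""


# ---------------------------------------------------------------------------
# 2. Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IIDRSetting:
    """One sound-processor program: the T-SPL/C-SPL pair defining the IIDR.

    ``t_spl`` is the acoustic level mapped to the electrical threshold (T)
    level, ``c_spl`` the level mapped to the loud-but-comfortable (C) level,
    both in dB SPL. The IIDR width is ``c_spl - t_spl``.
    """

    label: str
    t_spl: float
    c_spl: float

    def __post_init__(self) -> None:
        if self.label not in ("default", "wide"):
            raise ValidationError(f"unknown IIDR label {self.label!r}")
        if not self.c_spl > self.t_spl:
            raise ValidationError(
                f"C-SPL ({self.c_spl}) must exceed T-SPL ({self.t_spl})"
            )

    @property
    def width_db(self) -> float:
        return self.c_spl - self.t_spl


#: The study presets: default 25/65 (40 dB wide) and wide 25/80 (55 dB wide).
DEFAULT_IIDR = IIDRSetting("default", 25.0, 65.0)
WIDE_IIDR = IIDRSetting("wide", 25.0, 80.0)
IIDR_PRESETS: Mapping[str, IIDRSetting] = {"default": DEFAULT_IIDR, "wide": WIDE_IIDR}


def iidr_width(setting: IIDRSetting) -> float:
    """IIDR width in dB: the span between C-SPL and T-SPL."""
    return setting.width_db


@dataclass(frozen=True, order=True)
class TestCondition:
    """One test cell: material x environment x presentation level (x IIDR).

    ``iidr`` is the program label under which the list was administered; it
    is ``None`` for a *base* condition, the unit at which programs or groups
    are compared. ``snr_db`` is present only in noise (always +10 dB in the
    study presets).
    """

    __test__ = False  # not a test class despite the name

    material: str
    environment: str
    level_db_spl: int
    iidr: str | None = None
    snr_db: int | None = None

    def __post_init__(self) -> None:
        if self.material not in ITEMS_PER_MATERIAL:
            raise ValidationError(f"unknown material {self.material!r}")
        if self.environment not in ("quiet", "noise"):
            raise ValidationError(f"unknown environment {self.environment!r}")
        if self.iidr is not None and self.iidr not in IIDR_PRESETS:
            raise ValidationError(f"unknown IIDR label {self.iidr!r}")
        if self.environment == "quiet":
            if self.snr_db is not None:
                raise ValidationError("quiet conditions carry no SNR")
        elif self.snr_db is None:
            object.__setattr__(self, "snr_db", STUDY_SNR_DB)

    @property
    def n_items(self) -> int:
        return ITEMS_PER_MATERIAL[self.material]

    def with_iidr(self, label: str) -> "TestCondition":
        return replace(self, iidr=label)

    def base(self) -> "TestCondition":
        """The condition with the IIDR facet stripped."""
        return replace(self, iidr=None)

    def describe(self) -> str:
        env = f"{self.environment}" + (
            f" (SNR +{self.snr_db} dB)" if self.environment == "noise" else ""
        )
        tail = f", {self.iidr} IIDR" if self.iidr else ""
        return f"{self.material}s in {env} at {self.level_db_spl} dB SPL{tail}"


def study_conditions(with_iidr: bool = False) -> list[TestCondition]:
    """The 8 base test conditions (or all 16 IIDR-specific cells)."""
    base = [
        TestCondition(material=m, environment=e, level_db_spl=lv)
        for lv in STUDY_LEVELS_DB_SPL
        for m in ("word", "sentence")
        for e in ("quiet", "noise")
    ]
    if not with_iidr:
        return base
    return [c.with_iidr(lab) for c in base for lab in ("default", "wide")]


def _as_binary_array(values: Sequence[int] | np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValidationError(f"{what} is empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{what} contains non-binary values")
    return arr.astype(np.int8)


@dataclass(frozen=True)
class ItemResponseVector:
    """One subject's binary item outcomes for one (condition, IIDR) cell.

    Word cells hold 25 word outcomes; sentence cells hold 60 morpheme
    outcomes (1 = correct, 0 = incorrect).
    """

    subject_id: str
    group: str
    condition: TestCondition
    responses: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in STUDY_GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        arr = _as_binary_array(
            self.responses, f"responses for {self.subject_id}/{self.condition}"
        )
        expected = self.condition.n_items
        if arr.size != expected:
            raise ValidationError(
                f"cell {self.subject_id} / {self.condition.describe()} has "
                f"{arr.size} items, expected {expected}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "responses", arr)

    @property
    def n_correct(self) -> int:
        return int(self.responses.sum())


def score_percent(v: ItemResponseVector) -> float:
    """Percent-correct score: 100 x (correct items) / (items in the list)."""
    return 100.0 * v.n_correct / v.responses.size


@dataclass
class Cohort:
    """A fully crossed set of subjects: one response vector per cell.

    ``groups`` maps subject_id -> group label (stable insertion order defines
    subject order); ``cells`` maps (subject_id, IIDR-specific condition) ->
    ItemResponseVector.  Every subject must hold a vector for both IIDR
    settings in every base condition present in the cohort.
    """

    groups: dict[str, str]
    cells: dict[tuple[str, TestCondition], ItemResponseVector]

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ----------------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return list(self.groups)

    def subjects_in(self, grouping: str) -> list[str]:
        """Subject ids selected by a grouping label (``all`` or a group)."""
        if grouping == "all":
            return self.subject_ids
        if grouping not in STUDY_GROUPS:
            raise ValidationError(f"unknown grouping {grouping!r}")
        return [s for s, g in self.groups.items() if g == grouping]

    def base_conditions(self) -> list[TestCondition]:
        seen = sorted({cond.base() for _, cond in self.cells})
        return seen

    def cell(self, subject_id: str, condition: TestCondition) -> ItemResponseVector:
        try:
            return self.cells[(subject_id, condition)]
        except KeyError:
            raise ValidationError(
                f"missing cell: subject {subject_id!r}, {condition.describe()}"
            ) from None

    def vectors(self) -> Iterator[ItemResponseVector]:
        yield from self.cells.values()

    def validate(self) -> None:
        missing = []
        for (sid, cond), vec in self.cells.items():
            if sid not in self.groups:
                raise ValidationError(f"cell for unknown subject {sid!r}")
            if cond.iidr is None:
                raise ValidationError(
                    f"cell condition must carry an IIDR label: {cond}"
                )
            if vec.subject_id != sid or vec.condition != cond:
                raise ValidationError(f"mislabelled cell for subject {sid!r}")
            if vec.group != self.groups[sid]:
                raise ValidationError(
                    f"subject {sid!r} carries conflicting group labels"
                )
        for sid in self.groups:
            for cond in self.base_conditions():
                for lab in ("default", "wide"):
                    if (sid, cond.with_iidr(lab)) not in self.cells:
                        missing.append(f"{sid}: {cond.with_iidr(lab).describe()}")
        if missing:
            raise ValidationError(
                "cohort is not fully crossed; missing cells: " + "; ".join(missing)
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.groups == other.groups
            and self.cells.keys() == other.cells.keys()
            and all(
                np.array_equal(v.responses, other.cells[k].responses)
                for k, v in self.cells.items()
            )
        )


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one permutation test.

    ``observed_statistic`` is the mean-score difference in percentage points
    (comparison minus reference); ``extreme_count`` is the number of resampled
    (or enumerated) splits whose statistic met the inclusive extremity rule;
    ``p_value`` is ``extreme_count / n_resamples`` (Monte Carlo) or
    ``extreme_count / total assignments`` (exact).
    """

    observed_statistic: float
    n_resamples: int
    extreme_count: int
    p_value: float
    alternative: str
    seed: int | None
    mode: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    def annotate(self) -> str:
        """Human-readable p, flagging Monte Carlo zeros as '< 1/n'."""
        if self.mode == "monte_carlo" and self.extreme_count == 0:
            return f"< {1.0 / self.n_resamples:g}"
        return f"{self.p_value:g}"

    def to_dict(self) -> dict:
        return {
            "observed_statistic": self.observed_statistic,
            "n_resamples": self.n_resamples,
            "extreme_count": self.extreme_count,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "seed": self.seed,
            "mode": self.mode,
        }


# ---------------------------------------------------------------------------
# 3. Long-format CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "subject_id",
    "group",
    "material",
    "environment",
    "snr_db",
    "level_db_spl",
    "iidr",
    "item_index",
    "correct",
]

_CELL_KEYS = ["subject_id", "group", "material", "environment", "level_db_spl", "iidr"]


def read_responses(path: str | Path) -> Cohort:
    """Read a long-format item-response table into a validated Cohort.

    One row per subject x IIDR setting x condition x item; ``item_index``
    must form a contiguous 0-based run of the material's item count within
    each cell, and ``correct`` must be 0 or 1.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "snr_db"]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "snr_db" not in df.columns:
        df["snr_db"] = np.nan

    bad = ~df["correct"].isin((0, 1))
    if bad.any():
        # +2: 1-based data rows under a header line.
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValidationError(
            f"non-binary 'correct' value on row {row}: {df['correct'][bad].iloc[0]!r}"
        )

    group_counts = df.groupby("subject_id")["group"].nunique()
    conflicted = group_counts[group_counts > 1]
    if not conflicted.empty:
        raise ValidationError(
            f"conflicting group labels for subject(s): "
            f"{', '.join(map(str, conflicted.index))}"
        )

    groups: dict[str, str] = {}
    cells: dict[tuple[str, TestCondition], ItemResponseVector] = {}
    for key, sub in df.groupby(_CELL_KEYS, sort=False):
        sid, group, material, environment, level, iidr = key
        sid = str(sid)
        snr = sub["snr_db"].dropna().unique()
        cond = TestCondition(
            material=str(material),
            environment=str(environment),
            level_db_spl=int(level),
            iidr=str(iidr),
            snr_db=int(snr[0]) if snr.size else None,
        )
        expected = cond.n_items
        idx = np.sort(sub["item_index"].to_numpy())
        if len(sub) != expected or not np.array_equal(idx, np.arange(expected)):
            raise ValidationError(
                f"cell subject {sid!r} / {cond.describe()} has {len(sub)} rows "
                f"with item_index {sorted(set(idx.tolist()))[:5]}...; expected a "
                f"contiguous 0-based run of {expected}"
            )
        ordered = sub.sort_values("item_index")["correct"].to_numpy()
        groups.setdefault(sid, str(group))
        cells[(sid, cond)] = ItemResponseVector(sid, str(group), cond, ordered)
    return Cohort(groups=groups, cells=cells)


def write_responses(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as the canonical long-format CSV (one row per item)."""
    records = []
    for vec in cohort.vectors():
        cond = vec.condition
        for i, correct in enumerate(vec.responses):
            records.append(
                (
                    vec.subject_id,
                    vec.group,
                    cond.material,
                    cond.environment,
                    cond.snr_db if cond.snr_db is not None else "",
                    cond.level_db_spl,
                    cond.iidr,
                    i,
                    int(correct),
                )
            )
    pd.DataFrame(records, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# 4. Synthetic cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``accuracy`` maps (group, IIDR-specific condition) to the base probability
    that a single item is answered correctly.  ``subject_sd`` is the standard
    deviation of a per-subject random effect on the logit scale, shared across
    all of a subject's cells, so a subject who outperforms their group's mean
    does so consistently across lists and programs.
    """

    n_per_group: Mapping[str, int]
    accuracy: Mapping[tuple[str, TestCondition], float]
    subject_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ValidationError("subject_sd must be >= 0")
        for g, n in self.n_per_group.items():
            if g not in STUDY_GROUPS:
                raise ValidationError(f"unknown group {g!r}")
            if n < 0:
                raise ValidationError(f"negative group size for {g!r}")
        for (g, cond), p in self.accuracy.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"accuracy for ({g}, {cond.describe()}) outside [0, 1]: {p}"
                )
            if cond.iidr is None:
                raise ValidationError("accuracy keys must carry an IIDR label")

    # -- JSON interchange ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "n_per_group": dict(self.n_per_group),
            "subject_sd": self.subject_sd,
            "seed": self.seed,
            "accuracy": [
                {
                    "group": g,
                    "material": c.material,
                    "environment": c.environment,
                    "level_db_spl": c.level_db_spl,
                    "iidr": c.iidr,
                    "snr_db": c.snr_db,
                    "p": p,
                }
                for (g, c), p in self.accuracy.items()
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        payload = json.loads(text)
        accuracy = {
            (
                rec["group"],
                TestCondition(
                    material=rec["material"],
                    environment=rec["environment"],
                    level_db_spl=rec["level_db_spl"],
                    iidr=rec["iidr"],
                    snr_db=rec.get("snr_db"),
                ),
            ): rec["p"]
            for rec in payload["accuracy"]
        }
        return cls(
            n_per_group=payload["n_per_group"],
            accuracy=accuracy,
            subject_sd=payload.get("subject_sd", 0.2),
            seed=payload.get("seed", 0),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def figure3_preset(subject_sd: float = 0.2, seed: int = 0) -> GeneratorConfig:
    """The bundled study preset: 5+6 subjects, cell accuracies set to the
    published group/condition mean scores divided by 100."""
    accuracy = {
        (group, TestCondition(material=m, environment=e, level_db_spl=lv, iidr=lab)):
            mean / 100.0
        for (group, m, e, lv, lab), mean in FIGURE3_GROUP_MEANS.items()
    }
    return GeneratorConfig(
        n_per_group=dict(STUDY_GROUP_SIZES),
        accuracy=accuracy,
        subject_sd=subject_sd,
        seed=seed,
    )


def generate_item_responses(
    p: float, n_items: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw one list: ``n_items`` independent Bernoulli(p) item outcomes."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"success probability {p} outside [0, 1]")
    if n_items < 1:
        raise ValidationError("n_items must be positive")
    return (rng.random(n_items) < p).astype(np.int8)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# Stream-key constants: every random draw in a cohort comes from its own
# Generator seeded by [seed, stream, subject index, *cell key], so adding a
# condition or subject never perturbs other cells' draws.
_STREAM_SUBJECT_EFFECT = 0
_STREAM_ITEMS = 1
_COND_CODE = {
    ("word", "quiet"): 0,
    ("word", "noise"): 1,
    ("sentence", "quiet"): 2,
    ("sentence", "noise"): 3,
}


def _cell_stream(seed: int, subj_index: int, cond: TestCondition) -> np.random.Generator:
    code = _COND_CODE[(cond.material, cond.environment)]
    iidr_code = 0 if cond.iidr == "default" else 1
    return np.random.default_rng(
        [seed, _STREAM_ITEMS, subj_index, code, cond.level_db_spl, iidr_code]
    )


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a fully crossed synthetic cohort.

    Each subject receives a logit-normal random effect ``u_s`` shared across
    cells; the effective per-cell accuracy is
    ``inv_logit(logit(p_base) + u_s)``, with base probabilities of exactly 0
    or 1 passed through untouched (a floor/ceiling cell stays at the
    floor/ceiling).  Item outcomes are independent Bernoulli draws.
    Bitwise reproducible from ``config.seed``.
    """
    conditions = sorted({cond for (_, cond) in config.accuracy})
    groups: dict[str, str] = {}
    cells: dict[tuple[str, TestCondition], ItemResponseVector] = {}
    subj_index = 0
    for group in STUDY_GROUPS:
        n = config.n_per_group.get(group, 0)
        for k in range(n):
            sid = f"{group}_{k + 1:02d}"
            groups[sid] = group
            u_rng = np.random.default_rng(
                [config.seed, _STREAM_SUBJECT_EFFECT, subj_index]
            )
            u = float(u_rng.normal(0.0, config.subject_sd)) if config.subject_sd else 0.0
            for cond in conditions:
                if (group, cond) not in config.accuracy:
                    raise ValidationError(
                        f"no accuracy configured for ({group}, {cond.describe()})"
                    )
                p_base = config.accuracy[(group, cond)]
                p_eff = p_base if p_base in (0.0, 1.0) else _inv_logit(_logit(p_base) + u)
                rng = _cell_stream(config.seed, subj_index, cond)
                responses = generate_item_responses(p_eff, cond.n_items, rng)
                cells[(sid, cond)] = ItemResponseVector(sid, group, cond, responses)
            subj_index += 1
    return Cohort(groups=groups, cells=cells)


# ---------------------------------------------------------------------------
# 5. Permutation engine
# ---------------------------------------------------------------------------


def observed_mean_difference(
    a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray
) -> float:
    """Mean-score difference in percentage points, comparison minus reference.

    ``a`` is the reference condition (default IIDR, or the first group) and
    ``b`` the comparison condition (wide IIDR, or the second group).
    """
    a = _as_binary_array(a, "a")
    b = _as_binary_array(b, "b")
    return 100.0 * (b.mean() - a.mean())


def _check_alternative(alternative: str) -> None:
    if alternative not in ("greater", "two_sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")


def _diff_from_counts(k_b: np.ndarray | int, ones: int, na: int, nb: int) -> np.ndarray:
    """Mean difference (pp) of a split placing ``k_b`` ones in pseudo-b."""
    k_b = np.asarray(k_b, dtype=np.int64)
    return 100.0 * (k_b / nb - (ones - k_b) / na)


def mc_permutation_test(
    a: Sequence[int] | np.ndarray,
    b: Sequence[int] | np.ndarray,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = None,
    alternative: str = "greater",
) -> PermutationResult:
    """Monte Carlo permutation test of the mean-score difference.

    The two item-outcome vectors are pooled; each of ``n_resamples``
    independent iterations draws, without replacement, a pseudo-``b`` of size
    ``len(b)`` (the remainder is pseudo-``a``) and records the permuted mean
    difference.  The extremity rule is inclusive: a resample counts as extreme
    when its difference is >= the observed one (``greater``) or when its
    absolute difference is >= the observed absolute difference
    (``two_sided``).  ``p = extreme_count / n_resamples`` with no continuity
    correction, so p = 0 is possible and is annotated as ``< 1/n_resamples``
    in reports.

    Because the outcomes are binary, a without-replacement split is fully
    characterised by the number of ones landing in pseudo-``b``, which is
    drawn directly from the corresponding hypergeometric law; this is the
    identical resampling distribution, computed without materialising index
    permutations.
    """
    _check_alternative(alternative)
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    a = _as_binary_array(a, "a")
    b = _as_binary_array(b, "b")
    observed = 100.0 * (b.mean() - a.mean())

    na, nb = a.size, b.size
    ones = int(a.sum() + b.sum())
    rng = np.random.default_rng(seed)
    k_b = rng.hypergeometric(ones, na + nb - ones, nb, size=n_resamples)
    permuted = _diff_from_counts(k_b, ones, na, nb)
    if alternative == "greater":
        extreme = int(np.count_nonzero(permuted >= observed))
    else:
        extreme = int(np.count_nonzero(np.abs(permuted) >= abs(observed)))
    return PermutationResult(
        observed_statistic=observed,
        n_resamples=n_resamples,
        extreme_count=extreme,
        p_value=extreme / n_resamples,
        alternative=alternative,
        seed=seed,
        mode="monte_carlo",
    )


def exact_permutation_test(
    a: Sequence[int] | np.ndarray,
    b: Sequence[int] | np.ndarray,
    alternative: str = "greater",
    max_assignments: int = 10_000_000,
) -> PermutationResult:
    """Exhaustive-enumeration permutation test (the Monte Carlo oracle).

    Every distinct assignment of the pooled items to a pseudo-``b`` of size
    ``len(b)`` is enumerated.  For binary data an assignment is determined by
    the count ``k`` of ones placed in pseudo-``b``; each ``k`` carries
    ``C(ones, k) * C(zeros, nb - k)`` assignments, and the p-value is the
    exact integer ratio of extreme assignments to ``C(n, nb)``.
    """
    _check_alternative(alternative)
    a = _as_binary_array(a, "a")
    b = _as_binary_array(b, "b")
    na, nb = a.size, b.size
    n = na + nb
    total = math.comb(n, nb)
    if total > max_assignments:
        raise CapacityError(
            f"{total} assignments exceed the cap of {max_assignments}; "
            "use mc_permutation_test instead"
        )
    ones = int(a.sum() + b.sum())
    zeros = n - ones
    observed = 100.0 * (b.mean() - a.mean())

    extreme = 0
    for k in range(max(0, nb - zeros), min(nb, ones) + 1):
        diff = float(_diff_from_counts(k, ones, na, nb))
        is_extreme = (
            diff >= observed
            if alternative == "greater"
            else abs(diff) >= abs(observed) - 1e-12
        )
        if is_extreme:
            extreme += math.comb(ones, k) * math.comb(zeros, nb - k)
    return PermutationResult(
        observed_statistic=observed,
        n_resamples=total,
        extreme_count=extreme,
        p_value=extreme / total,
        alternative=alternative,
        seed=None,
        mode="exact",
    )


def pool_cell(
    cohort: Cohort, spec: "ComparisonSpec"
) -> tuple[np.ndarray, np.ndarray]:
    """Pool item outcomes across subjects into the two comparison sides.

    Within-IIDR comparisons fix the base condition and return
    (default-program items, wide-program items) concatenated over the
    selected subjects in stable subject order.  Between-group comparisons fix
    both the condition and the program and return (preCSPL65 items,
    preCSPL80 items).
    """
    if spec.axis == "within_iidr":
        subjects = cohort.subjects_in(spec.grouping)
        if not subjects:
            raise ValidationError(f"grouping {spec.grouping!r} selects no subject")
        sides = [
            (subjects, spec.condition.with_iidr("default")),
            (subjects, spec.condition.with_iidr("wide")),
        ]
    else:
        cond = spec.condition.with_iidr(spec.fixed_iidr)
        sides = [
            (cohort.subjects_in("preCSPL65"), cond),
            (cohort.subjects_in("preCSPL80"), cond),
        ]
        if not all(subs for subs, _ in sides):
            raise ValidationError("between-group comparison with an empty group")
    pooled = tuple(
        np.concatenate([cohort.cell(s, cond).responses for s in subs])
        for subs, cond in sides
    )
    return pooled  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# 6. Study pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class ComparisonSpec:
    """One cell of the comparison matrix.

    ``within_iidr`` compares the default vs the wide program at a fixed base
    condition for a grouping (all subjects or one preference group);
    ``between_group`` compares the two preference groups at a fixed condition
    and program.
    """

    grouping: str
    axis: str
    condition: TestCondition
    fixed_iidr: str | None = None

    def __post_init__(self) -> None:
        if self.grouping not in ("all",) + STUDY_GROUPS:
            raise ValidationError(f"unknown grouping {self.grouping!r}")
        if self.axis not in ("within_iidr", "between_group"):
            raise ValidationError(f"unknown axis {self.axis!r}")
        if self.condition.iidr is not None:
            raise ValidationError("ComparisonSpec conditions carry no IIDR facet")
        if self.axis == "between_group":
            if self.grouping != "all":
                raise ValidationError("between-group comparisons use grouping='all'")
            if self.fixed_iidr not in IIDR_PRESETS:
                raise ValidationError("between-group comparisons need a fixed IIDR")
        elif self.fixed_iidr is not None:
            raise ValidationError("within-IIDR comparisons take no fixed IIDR")

    @property
    def sides(self) -> tuple[str, str]:
        if self.axis == "within_iidr":
            return ("default", "wide")
        return ("preCSPL65", "preCSPL80")

    def key(self) -> tuple:
        c = self.condition
        return (
            self.grouping,
            self.axis,
            c.material,
            c.environment,
            c.level_db_spl,
            self.fixed_iidr,
        )


def default_comparison_matrix() -> list[ComparisonSpec]:
    """The full study matrix: 24 within-IIDR + 16 between-group comparisons.

    Within-IIDR: 4 condition types x 2 levels x 3 groupings (all subjects and
    each preference group).  Between-group: 4 condition types x 2 levels x 2
    fixed programs.
    """
    specs = [
        ComparisonSpec(grouping=g, axis="within_iidr", condition=cond)
        for g in ("all", "preCSPL65", "preCSPL80")
        for cond in study_conditions()
    ]
    specs += [
        ComparisonSpec(
            grouping="all", axis="between_group", condition=cond, fixed_iidr=lab
        )
        for lab in ("default", "wide")
        for cond in study_conditions()
    ]
    return specs


@dataclass
class StudyReport:
    """The comparison-matrix results: one row per executed ComparisonSpec.

    ``table`` columns: the spec key facets, side means (%), observed
    difference (pp), p-value, significance flags at 0.05 and 0.01 (strict
    ``<``), extreme count, resample count and per-comparison seed.
    ``meta`` carries run provenance (base seed, resample count, alternative,
    generator config hash when synthetic, package version).
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "StudyReport":
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition(": ")
            meta[k] = v
        from io import StringIO

        table = pd.read_csv(StringIO("".join(l for l in lines if not l.startswith("#"))))
        return cls(table=table, meta=meta)

    def summary(self) -> str:
        """Human-readable per-comparison lines."""
        out = []
        for _, r in self.table.iterrows():
            stars = "**" if r["sig_0.01"] else ("*" if r["sig_0.05"] else "ns")
            cond = f"{r['material']}s in {r['environment']} at {r['level_db_spl']} dB"
            facet = (
                f"{r['grouping']}, default vs wide IIDR"
                if r["axis"] == "within_iidr"
                else f"groups at {r['fixed_iidr']} IIDR"
            )
            out.append(
                f"{cond:38s} [{facet:28s}] "
                f"{r['mean_a']:6.1f}% -> {r['mean_b']:6.1f}% "
                f"(diff {r['observed_diff']:+6.1f} pp, p = {r['p_annotated']}) {stars}"
            )
        return "\n".join(out)


def summarize_means(cohort: Cohort, grouping: str = "all") -> pd.DataFrame:
    """Per-cell unweighted mean percent score over the selected subjects."""
    subjects = cohort.subjects_in(grouping)
    if not subjects:
        raise ValidationError(f"grouping {grouping!r} selects no subject")
    rows = []
    for cond in cohort.base_conditions():
        for lab in ("default", "wide"):
            cell = cond.with_iidr(lab)
            mean = float(
                np.mean([score_percent(cohort.cell(s, cell)) for s in subjects])
            )
            rows.append(
                {
                    "grouping": grouping,
                    "material": cond.material,
                    "environment": cond.environment,
                    "level_db_spl": cond.level_db_spl,
                    "iidr": lab,
                    "mean_percent": mean,
                    "n_subjects": len(subjects),
                }
            )
    return pd.DataFrame(rows)


def _comparison_seeds(seed: int | None, n: int) -> list[int | None]:
    if seed is None:
        return [None] * n
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def run_study(
    cohort: Cohort,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = 0,
    alternative: str = "greater",
    matrix: Sequence[ComparisonSpec] | None = None,
    meta: Mapping | None = None,
) -> StudyReport:
    """Run the full comparison matrix over a cohort.

    Each comparison pools the relevant item outcomes and runs one Monte Carlo
    permutation test; per-comparison seeds are spawned deterministically from
    ``seed``, so a rerun reproduces every p-value bit-exactly.
    """
    specs = list(matrix) if matrix is not None else default_comparison_matrix()
    seeds = _comparison_seeds(seed, len(specs))
    subject_means = {
        g: summarize_means(cohort, g) for g in ("all",) + STUDY_GROUPS
    }

    def _cell_mean(grouping: str, cond: TestCondition, lab: str) -> float:
        df = subject_means[grouping]
        m = df[
            (df["material"] == cond.material)
            & (df["environment"] == cond.environment)
            & (df["level_db_spl"] == cond.level_db_spl)
            & (df["iidr"] == lab)
        ]
        return float(m["mean_percent"].iloc[0])

    rows = []
    for spec, s in zip(specs, seeds):
        a, b = pool_cell(cohort, spec)
        res = mc_permutation_test(
            a, b, n_resamples=n_resamples, seed=s, alternative=alternative
        )
        if spec.axis == "within_iidr":
            mean_a = _cell_mean(spec.grouping, spec.condition, "default")
            mean_b = _cell_mean(spec.grouping, spec.condition, "wide")
        else:
            mean_a = _cell_mean("preCSPL65", spec.condition, spec.fixed_iidr)
            mean_b = _cell_mean("preCSPL80", spec.condition, spec.fixed_iidr)
        rows.append(
            {
                "grouping": spec.grouping,
                "axis": spec.axis,
                "material": spec.condition.material,
                "environment": spec.condition.environment,
                "level_db_spl": spec.condition.level_db_spl,
                "fixed_iidr": spec.fixed_iidr,
                "side_a": spec.sides[0],
                "side_b": spec.sides[1],
                "mean_a": mean_a,
                "mean_b": mean_b,
                "observed_diff": res.observed_statistic,
                "p_value": res.p_value,
                "p_annotated": res.annotate(),
                "sig_0.05": res.p_value < 0.05,
                "sig_0.01": res.p_value < 0.01,
                "extreme_count": res.extreme_count,
                "n_resamples": res.n_resamples,
                "seed": s,
            }
        )
    table = pd.DataFrame(rows)
    full_meta = {
        "version": __version__,
        "seed": seed,
        "n_resamples": n_resamples,
        "alternative": alternative,
        "n_comparisons": len(specs),
    }
    if meta:
        full_meta.update(meta)
    return StudyReport(table=table, meta=full_meta)


def significance_pattern(
    report: StudyReport, alpha: float = 0.05
) -> dict[tuple, bool]:
    """Map each comparison key to ``p < alpha`` (strict inequality)."""
    return {
        (
            r["grouping"],
            r["axis"],
            r["material"],
            r["environment"],
            int(r["level_db_spl"]),
            None if pd.isna(r["fixed_iidr"]) else r["fixed_iidr"],
        ): bool(r["p_value"] < alpha)
        for _, r in report.table.iterrows()
    }


def pattern_diff(
    observed: Mapping[tuple, bool], expected: Mapping[tuple, bool]
) -> dict[tuple, tuple[bool, bool]]:
    """Comparisons where the observed significance flag disagrees with an
    expected pattern; empty when every expected key matches."""
    out = {}
    for key, want in expected.items():
        got = observed.get(key)
        if got != want:
            out[key] = (got, want)
    return out


def all_subjects_within_pattern(report: StudyReport, alpha: float = 0.05) -> dict:
    """The all-subjects within-IIDR significance pattern keyed like
    :data:`EXPECTED_PATTERN_ALL_SUBJECTS` ((material, environment, level))."""
    full = significance_pattern(report, alpha)
    return {
        (m, e, lv): sig
        for (g, axis, m, e, lv, _), sig in full.items()
        if g == "all" and axis == "within_iidr"
    }
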