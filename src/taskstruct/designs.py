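"""Trial-structure construction for the four learning/memory experiments.

Participants learn, by trial and error, to map four two-dimensional stimulus
categories (a full 2 x 2 cross of two binary feature dimensions, e.g. border
color x shape, or face age x gender) onto four response keys (v, b, n, m;
key positions 1-4 left to right).  The central manipulation is whether the
category-to-key assignment is *motor-clustered*: for clustered mappings the
two categories sharing each level of a "biased" (candidate supraordinate)
dimension sit on adjacent keys, which encourages participants to form a
hierarchical task-set; non-clustered mappings break that adjacency.

This module builds the mappings, the learning-phase trial lists (equal
category frequency, trial-unique images, seeded random order), the surprise
memory-phase lists (every old image plus ~1/3 new images), the Experiment-3
mid-phase rule switch, and the counterbalanced versions of each experiment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "ConfigurationError",
    "StimulusDimension",
    "Category",
    "ResponseMapping",
    "ExperimentDesign",
    "KEY_NAMES",
    "COLOR_SHAPE_DIMS",
    "AGE_GENDER_DIMS",
    "build_response_mapping",
    "generate_learning_trials",
    "apply_rule_switch",
    "transfer_classification",
    "generate_memory_trials",
    "n_new_images",
    "mean_key_distance",
    "enumerate_versions",
    "build_face_catalog",
    "required_sample_size",
    "design_to_frame",
    "save_design",
]


class DesignError(ValueError):
    """Raised when a trial structure violates a design invariant."""


class ConfigurationError(ValueError):
    """Raised for inconsistent user-supplied configuration."""


#: Physical keys at positions 1-4 (right index / middle / ring / pinky).
KEY_NAMES = ("v", "b", "n", "m")


@dataclass(frozen=True)
class StimulusDimension:
    """A binary stimulus feature dimension (e.g. color: red/blue)."""

    name: str
    levels: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.levels) != 2 or len(set(self.levels)) != 2:
            raise ConfigurationError(
                f"dimension {self.name!r} must have exactly 2 distinct levels"
            )


@dataclass(frozen=True)
class Category:
    """One stimulus category: a level on each of the two dimensions.

    ``level1``/``level2`` are aligned with the design's ``dims`` order.
    """

    level1: str
    level2: str

    def level_on(self, dim_index: int) -> str:
        return (self.level1, self.level2)[dim_index]

    def label(self) -> str:
        return f"{self.level1}-{self.level2}"


def _all_categories(dims: tuple[StimulusDimension, StimulusDimension]) -> list[Category]:
    return [Category(l1, l2) for l1 in dims[0].levels for l2 in dims[1].levels]


@dataclass(frozen=True)
class ResponseMapping:
    """Bijective assignment of the four categories to key positions 1-4."""

    assignment: dict[Category, int]
    clustered: bool
    biased_dimension: str
    dims: tuple[StimulusDimension, StimulusDimension]

    def __post_init__(self) -> None:
        cats = set(_all_categories(self.dims))
        if set(self.assignment) != cats:
            raise DesignError("mapping must cover exactly the 2x2 category cross")
        if sorted(self.assignment.values()) != [1, 2, 3, 4]:
            raise DesignError("mapping must be a bijection onto key positions {1,2,3,4}")
        if self.clustered and not self._is_clustered():
            raise DesignError(
                "clustered mapping must place same-level categories of the "
                "biased dimension on adjacent key pairs {1,2} and {3,4}"
            )

    def _biased_index(self) -> int:
        for i, d in enumerate(self.dims):
            if d.name == self.biased_dimension:
                return i
        raise ConfigurationError(
            f"unknown biased dimension {self.biased_dimension!r}; "
            f"expected one of {[d.name for d in self.dims]}"
        )

    def _is_clustered(self) -> bool:
        bi = self._biased_index()
        for level in self.dims[bi].levels:
            keys = sorted(
                k for c, k in self.assignment.items() if c.level_on(bi) == level
            )
            if keys not in ([1, 2], [3, 4]):
                return False
        return True

    def key_for(self, category: Category) -> int:
        return self.assignment[category]

    def key_name_for(self, category: Category) -> str:
        return KEY_NAMES[self.assignment[category] - 1]


def build_response_mapping(
    clustered: bool,
    biased_dimension: str,
    dims: tuple[StimulusDimension, StimulusDimension],
) -> ResponseMapping:
    """Construct the canonical clustered or non-clustered key assignment.

    With biased-dimension levels (B0, B1) and sub-dimension levels (S0, S1):

    * clustered:      B0S0->1, B0S1->2, B1S0->3, B1S1->4  (sub-dimension
      nested at adjacent keys within each biased level)
    * non-clustered:  B0S0->1, B0S1->4, B1S0->3, B1S1->2  (each biased
      level's pair split across non-adjacent keys)

    The non-clustered pattern follows the printed instruction examples
    ("if YOUNG, press v for female and m for male; if OLD, press n for
    female and b for male"); other non-adjacent bijections can be built
    directly via :class:`ResponseMapping`.
    """
    names = [d.name for d in dims]
    if biased_dimension not in names:
        raise ConfigurationError(
            f"unknown biased dimension {biased_dimension!r}; expected one of {names}"
        )
    bi = names.index(biased_dimension)
    si = 1 - bi
    b0, b1 = dims[bi].levels
    s0, s1 = dims[si].levels

    def cat(b_level: str, s_level: str) -> Category:
        levels = [None, None]
        levels[bi] = b_level
        levels[si] = s_level
        return Category(*levels)

    if clustered:
        order = [(b0, s0), (b0, s1), (b1, s0), (b1, s1)]
    else:
        order = [(b0, s0), (b1, s1), (b1, s0), (b0, s1)]
    assignment = {cat(b, s): pos for pos, (b, s) in enumerate(order, start=1)}
    return ResponseMapping(
        assignment=assignment,
        clustered=clustered,
        biased_dimension=biased_dimension,
        dims=dims,
    )


#: Experiment 1 dimensions: superficial border features around object images.
COLOR_SHAPE_DIMS = (
    StimulusDimension("color", ("red", "blue")),
    StimulusDimension("shape", ("square", "circle")),
)

#: Experiments 2-4 dimensions: inherent face features.
AGE_GENDER_DIMS = (
    StimulusDimension("age", ("young", "old")),
    StimulusDimension("gender", ("female", "male")),
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Full specification of one counterbalanced task version."""

    experiment_id: int
    n_learning_trials: int
    mapping: ResponseMapping
    version_id: int
    rule_switch_at: Optional[int] = None
    post_switch_mapping: Optional[ResponseMapping] = None
    instructed: bool = False
    source_memory: bool = False
    question_order: Optional[str] = None  # Exp 1: "color_first" | "shape_first"

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2, 3, 4):
            raise DesignError(f"unknown experiment id {self.experiment_id}")
        if self.n_learning_trials % 4:
            raise DesignError("n_learning_trials must be divisible by 4")
        if self.rule_switch_at is not None:
            if self.rule_switch_at != self.n_learning_trials // 2:
                raise DesignError("rule switch must occur exactly halfway")

    @property
    def dims(self) -> tuple[StimulusDimension, StimulusDimension]:
        return self.mapping.dims

    @property
    def n_memory_new(self) -> int:
        return n_new_images(self.n_learning_trials, n_categories=4)

    def mapping_at(self, trial_index: int) -> ResponseMapping:
        """Active mapping on 1-based learning trial ``trial_index``."""
        if (
            self.rule_switch_at is not None
            and self.post_switch_mapping is not None
            and trial_index > self.rule_switch_at
        ):
            return self.post_switch_mapping
        return self.mapping


def n_new_images(n_old: int, n_categories: int = 4) -> int:
    """Smallest multiple of ``n_categories`` at least ``n_old / 3``.

    Reconstructs the printed memory-phase compositions: 128 old -> 44 new
    (172 trials) and 120 old -> 40 new (160 trials).
    """
    return n_categories * math.ceil(n_old / 3 / n_categories)


def generate_learning_trials(
    design: ExperimentDesign, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Seeded random learning-phase trial list with equal category frequency.

    Returns a frame with 1-based ``trial``, the two level columns (named
    after the dimensions), a trial-unique integer ``image_id``, and the
    ``correct_key`` under the mapping active at that trial.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = design.n_learning_trials
    cats = _all_categories(design.dims)
    sequence = np.repeat(np.arange(4), n // 4)
    rng.shuffle(sequence)
    trial = np.arange(1, n + 1)
    pre_keys = np.array([design.mapping.key_for(c) for c in cats])
    correct = pre_keys[sequence]
    if design.rule_switch_at is not None and design.post_switch_mapping is not None:
        post_keys = np.array([design.post_switch_mapping.key_for(c) for c in cats])
        correct = np.where(
            trial > design.rule_switch_at, post_keys[sequence], correct
        )
    level1 = np.array([c.level1 for c in cats], dtype=object)[sequence]
    level2 = np.array([c.level2 for c in cats], dtype=object)[sequence]
    return pd.DataFrame(
        {
            "trial": trial,
            design.dims[0].name: level1,
            design.dims[1].name: level2,
            "image_id": trial,
            "correct_key": correct,
        }
    )


def apply_rule_switch(design: ExperimentDesign) -> ExperimentDesign:
    """Install the Experiment-3 halfway rule switch on a design.

    The post-switch mapping is the same canonical pattern rebuilt around the
    *other* stimulus dimension.  For clustered learners this flips the
    motor-clustered supraordinate dimension; for non-clustered learners it
    re-assigns one pair of category-key associations.  In both cases exactly
    two categories keep their key throughout ("positive transfer") and two
    change ("negative transfer").
    """
    if design.experiment_id != 3:
        raise DesignError("rule switch is defined only for experiment 3")
    names = [d.name for d in design.dims]
    other = names[1 - names.index(design.mapping.biased_dimension)]
    post = build_response_mapping(design.mapping.clustered, other, design.dims)
    switched = replace(
        design,
        rule_switch_at=design.n_learning_trials // 2,
        post_switch_mapping=post,
    )
    kept = transfer_classification(design.mapping, post)["positive"]
    if len(kept) != 2:
        raise DesignError(
            f"rule switch must preserve exactly 2 category-key pairs, got {len(kept)}"
        )
    return switched


def transfer_classification(
    pre: ResponseMapping, post: ResponseMapping
) -> dict[str, list[Category]]:
    """Split categories into positive (key kept) / negative (key changed) transfer."""
    if pre.dims != post.dims:
        raise DesignError("pre and post mappings must share the same dimensions")
    positive = [c for c in pre.assignment if pre.assignment[c] == post.assignment[c]]
    negative = [c for c in pre.assignment if c not in positive]
    if len(positive) == 4:
        raise DesignError("pre and post mappings are identical: no rule switch")
    return {"positive": positive, "negative": negative}


def generate_memory_trials(
    learning_trials: pd.DataFrame,
    design: ExperimentDesign,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Memory-phase list: every learning image (old) plus balanced new images.

    New-image count is the smallest multiple of the category count that is at
    least one third of the old count; new images are spread equally over
    categories.  Order is a seeded random permutation.  ``lp_trial`` records
    the learning-phase position of old items (NaN for new).
    """
    if learning_trials.empty:
        raise DesignError("learning trial list is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d1, d2 = design.dims[0].name, design.dims[1].name
    old = learning_trials[["image_id", d1, d2, "trial"]].rename(
        columns={"trial": "lp_trial"}
    )
    old = old.assign(status="old")
    cats = _all_categories(design.dims)
    n_new = n_new_images(len(old), n_categories=len(cats))
    per_cat = n_new // len(cats)
    next_id = int(learning_trials["image_id"].max()) + 1
    new = pd.DataFrame(
        {
            "image_id": np.arange(next_id, next_id + n_new),
            d1: np.repeat([c.level1 for c in cats], per_cat),
            d2: np.repeat([c.level2 for c in cats], per_cat),
            "lp_trial": np.nan,
            "status": "new",
        }
    )
    mem = pd.concat([old, new], ignore_index=True)
    mem = mem.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    mem.insert(0, "position", np.arange(1, len(mem) + 1))
    return mem


def mean_key_distance(mapping: ResponseMapping) -> float:
    """Mean keyboard distance over the four category pairs sharing a feature level.

    Keys sit at consecutive integer positions, so distance is the absolute
    key-position difference; the canonical clustered mapping yields distances
    (1, 1, 2, 2), mean 1.5.
    """
    distances = []
    for di in (0, 1):
        for level in mapping.dims[di].levels:
            keys = [
                k for c, k in mapping.assignment.items() if c.level_on(di) == level
            ]
            distances.append(abs(keys[0] - keys[1]))
    return float(np.mean(distances))


def enumerate_versions(experiment_id: int) -> list[ExperimentDesign]:
    """All counterbalanced task versions of an experiment.

    Experiment 1 crosses cluster group x biased dimension x source-question
    order (8 versions); Experiments 2-4 cross cluster group x biased
    dimension (4 versions).
    """
    if experiment_id not in (1, 2, 3, 4):
        raise DesignError(f"unknown experiment id {experiment_id}")
    dims = COLOR_SHAPE_DIMS if experiment_id == 1 else AGE_GENDER_DIMS
    n_trials = 128 if experiment_id == 1 else 120
    question_orders: list[Optional[str]] = (
        ["color_first", "shape_first"] if experiment_id == 1 else [None]
    )
    versions = []
    vid = 1
    for clustered in (True, False):
        for dim in dims:
            for qorder in question_orders:
                design = ExperimentDesign(
                    experiment_id=experiment_id,
                    n_learning_trials=n_trials,
                    mapping=build_response_mapping(clustered, dim.name, dims),
                    version_id=vid,
                    instructed=experiment_id == 4,
                    source_memory=experiment_id == 1,
                    question_order=qorder,
                )
                if experiment_id == 3:
                    design = apply_rule_switch(design)
                versions.append(design)
                vid += 1
    return versions


# Race composition of the face stimulus set, per category: 43 white faces
# plus 9 of other backgrounds, 52 per category, 208 total.
_FACE_COMPOSITION = {
    ("young", "female"): {
        "white": 43, "south_asian": 4, "hispanic": 3, "east_asian": 1, "black": 1,
    },
    ("old", "female"): {
        "white": 43, "east_asian": 4, "south_asian": 3, "middle_eastern": 2,
    },
    ("young", "male"): {"white": 43, "hispanic": 5, "south_asian": 4},
    ("old", "male"): {"white": 43, "middle_eastern": 5, "south_asian": 2, "east_asian": 2},
}


def build_face_catalog() -> pd.DataFrame:
    """Synthetic catalog of the 208-face stimulus set used in Experiments 2-4.

    Real images are out of scope; each row is a synthetic face entry with its
    age/gender category and race label, reproducing the documented category
    and race composition (4 categories x 52 faces).
    """
    rows = []
    face_id = 1
    for (age, gender), races in _FACE_COMPOSITION.items():
        for race, count in races.items():
            for _ in range(count):
                rows.append(
                    {"face_id": face_id, "age": age, "gender": gender, "race": race}
                )
                face_id += 1
    return pd.DataFrame(rows)


def required_sample_size(
    effect_size: float, power: float = 0.90, alpha: float = 0.05
) -> int:
    """Participants needed for a one-sample two-sided t-test at given power.

    Used for a priori power planning of switch-cost detection (e.g. the
    motor-clustered RT switch cost of d_z = 0.88 reported in earlier work).
    """
    from statsmodels.stats.power import TTestPower

    n = TTestPower().solve_power(
        effect_size=effect_size, power=power, alpha=alpha, alternative="two-sided"
    )
    return int(math.ceil(n))


def design_to_frame(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Serialize a design's trial lists to one long table (phase column)."""
    rng = np.random.default_rng(seed)
    lp = generate_learning_trials(design, rng)
    mp = generate_memory_trials(lp, design, rng)
    d1, d2 = design.dims[0].name, design.dims[1].name
    lp_out = lp.rename(columns={"trial": "trial_index", d1: "dim1_level", d2: "dim2_level"})
    lp_out = lp_out.assign(phase="learning", status="old")
    mp_out = mp.rename(
        columns={"position": "trial_index", d1: "dim1_level", d2: "dim2_level"}
    )
    mp_out = mp_out.assign(phase="memory", correct_key=np.nan)
    cols = ["phase", "trial_index", "dim1_level", "dim2_level", "image_id",
            "correct_key", "status"]
    return pd.concat([lp_out[cols], mp_out[cols]], ignore_index=True)


def save_design(design: ExperimentDesign, seed: int, out_dir: str | Path) -> None:
    """Write trial CSV plus a JSON sidecar with mapping/version metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = design_to_frame(design, seed)
    frame.to_csv(out / "design.csv", index=False)
    meta = {
        "experiment_id": design.experiment_id,
        "version_id": design.version_id,
        "seed": seed,
        "n_learning_trials": design.n_learning_trials,
        "n_memory_new": design.n_memory_new,
        "clustered": design.mapping.clustered,
        "biased_dimension": design.mapping.biased_dimension,
        "dimensions": [
            {"name": d.name, "levels": list(d.levels)} for d in design.dims
        ],
        "mapping": {c.label(): k for c, k in design.mapping.assignment.items()},
        "rule_switch_at": design.rule_switch_at,
        "post_switch_mapping": (
            {c.label(): k for c, k in design.post_switch_mapping.assignment.items()}
            if design.post_switch_mapping
            else None
        ),
        "instructed": design.instructed,
        "source_memory": design.source_memory,
        "question_order": design.question_order,
    }
    (out / "design_meta.json").write_text(json.dumps(meta, indent=2))
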