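"""Dirichlet-multinomial simulator of genus-abundance tables.

Each community class is a Dirichlet distribution over genera whose
signature genus gets its concentration multiplied by a dominance factor;
a sample draws its class from the mixing proportions, its genus
composition from the class Dirichlet, its read depth from a log-normal,
and its counts from a multinomial.  High dominance produces the
one-genus-dominated, low-diversity, tightly clustered profile of type I
habitats (vagina, retroauricular crease); low dominance the flat,
diverse, diffusely clustered type II profile (oral sites, stool).

Longitudinal tables re-draw each subject's visit-2 class from a
class-to-class switch matrix; metadata tables draw demographic factors
from class-conditional distributions so planted associations (or their
absence, for null calibration) are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .tables import CountTable, ValidationError

__all__ = [
    "DEFAULT_TAXA",
    "SyntheticSpec",
    "simulate_habitat",
    "simulate_longitudinal",
    "simulate_metadata",
    "type_I_vagina_like",
    "type_II_stool_like",
    "type_II_oral_like",
    "well_separated",
    "null_metadata_model",
    "planted_metadata_model",
]

#: 50 genus labels: common human-microbiome genera plus numbered filler
DEFAULT_TAXA = [
    "Bacteroides", "Prevotella", "Ruminococcus", "Lactobacillus",
    "Propionibacterium", "Staphylococcus", "Corynebacterium",
    "Streptococcus", "Moraxella", "Gardnerella", "Atopobium", "Veillonella",
    "Treponema", "Porphyromonas", "Neisseria", "Haemophilus",
    "Fusobacterium", "Actinomyces", "Sneathia", "Megasphaera", "Dialister",
    "Faecalibacterium", "Roseburia", "Blautia", "Clostridium",
    "Bifidobacterium", "Escherichia", "Akkermansia", "Alistipes",
    "Parabacteroides",
] + [f"Genus_{i:02d}" for i in range(31, 51)]


@dataclass
class SyntheticSpec:
    """Parameters of one simulated habitat.

    classes is a list of (signature genus, mixing weight) pairs; each
    class's Dirichlet concentration is ``base_concentration`` for every
    genus except the signature genus, which gets ``base_concentration *
    dominance``.  Read depths are log-normal with the given median and
    log-scale sigma (median 5,000 keeps rarefaction to 1,000 from
    dropping samples).
    """

    n_subjects: int = 200
    taxa: list[str] = field(default_factory=lambda: list(DEFAULT_TAXA))
    classes: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("Bacteroides", 0.6), ("Prevotella", 0.1), ("Ruminococcus", 0.3)
        ]
    )
    dominance: float = 100.0
    base_concentration: float = 0.1
    depth_median: float = 5000.0
    depth_sigma: float = 0.5
    switch_matrix: np.ndarray | None = None
    metadata_model: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not self.classes:
            raise ValidationError("at least one class is required")
        weights = np.array([w for _, w in self.classes], dtype=float)
        if (weights <= 0).any() or not np.isclose(weights.sum(), 1.0, atol=1e-9):
            raise ValidationError("class mixing weights must be positive and sum to 1")
        for sig, _ in self.classes:
            if sig not in self.taxa:
                raise ValidationError(f"signature genus {sig!r} not in taxa list")
        if not (self.dominance > 0 and self.base_concentration > 0):
            raise ValidationError("dominance and base_concentration must be positive")
        if self.switch_matrix is not None:
            sm = np.asarray(self.switch_matrix, dtype=float)
            k = len(self.classes)
            if sm.shape != (k, k):
                raise ValidationError(f"switch matrix must be {k}x{k}")
            if (sm < 0).any() or not np.allclose(sm.sum(axis=1), 1.0, atol=1e-9):
                raise ValidationError("switch matrix rows must be probabilities summing to 1")
            self.switch_matrix = sm

    @property
    def class_names(self) -> list[str]:
        return [sig for sig, _ in self.classes]

    def concentration(self, class_index: int) -> np.ndarray:
        alpha = np.full(len(self.taxa), self.base_concentration)
        sig = self.classes[class_index][0]
        alpha[self.taxa.index(sig)] = self.base_concentration * self.dominance
        return alpha


def _draw_samples(
    spec: SyntheticSpec, class_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n_taxa = len(spec.taxa)
    counts = np.zeros((len(class_idx), n_taxa), dtype=np.int64)
    mu = log(spec.depth_median)
    for i, c in enumerate(class_idx):
        props = rng.dirichlet(spec.concentration(int(c)))
        depth = max(1, int(round(rng.lognormal(mu, spec.depth_sigma))))
        counts[i] = rng.multinomial(depth, props)
    return counts


def simulate_habitat(spec: SyntheticSpec) -> tuple[CountTable, np.ndarray]:
    """Simulate one habitat; returns (counts, true class labels).

    Labels are the signature-genus names of the planted classes.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for _, w in spec.classes])
    class_idx = rng.choice(len(spec.classes), size=spec.n_subjects, p=weights)
    counts = _draw_samples(spec, class_idx, rng)
    ids = [f"S{i + 1:04d}" for i in range(spec.n_subjects)]
    labels = np.array([spec.class_names[c] for c in class_idx])
    return CountTable(ids, list(spec.taxa), counts), labels


def simulate_longitudinal(
    spec: SyntheticSpec,
) -> tuple[CountTable, CountTable, np.ndarray, np.ndarray]:
    """Two visits of the same subjects with class switching.

    Visit-1 classes follow the mixing proportions; each subject's
    visit-2 class is drawn from the switch-matrix row of its visit-1
    class and its abundances are re-drawn from the visit-2 class.
    Returns (visit1, visit2, labels1, labels2) with shared subject ids.
    """
    if spec.switch_matrix is None:
        raise ValidationError("spec.switch_matrix is required for longitudinal data")
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for _, w in spec.classes])
    k = len(spec.classes)
    idx1 = rng.choice(k, size=spec.n_subjects, p=weights)
    counts1 = _draw_samples(spec, idx1, rng)
    idx2 = np.array(
        [rng.choice(k, p=spec.switch_matrix[c]) for c in idx1]
    )
    counts2 = _draw_samples(spec, idx2, rng)
    ids = [f"S{i + 1:04d}" for i in range(spec.n_subjects)]
    names = spec.class_names
    return (
        CountTable(ids, list(spec.taxa), counts1),
        CountTable(ids, list(spec.taxa), counts2),
        np.array([names[c] for c in idx1]),
        np.array([names[c] for c in idx2]),
    )


def simulate_metadata(
    labels: np.ndarray, spec: SyntheticSpec, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Draw per-subject metadata from class-conditional distributions.

    The model maps each factor to either a categorical entry — levels
    plus per-class (or "default") level probabilities — or a continuous
    entry with per-class (or "default") means and a common sd.
    """
    model = spec.metadata_model
    if not model:
        raise ValidationError("spec.metadata_model is required")
    rng = np.random.default_rng([spec.seed, 1009])
    n = len(labels)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    out = {}
    for factor, fs in model.items():
        kind = fs.get("type")
        if kind == "categorical":
            levels = fs["levels"]
            col = []
            for lab in labels:
                probs = fs["probs"].get(lab, fs["probs"].get("default"))
                if probs is None:
                    raise ValidationError(
                        f"factor {factor!r}: no probabilities for class {lab!r}"
                    )
                col.append(levels[rng.choice(len(levels), p=probs)])
            out[factor] = col
        elif kind == "continuous":
            means = fs["mean"]
            sd = fs["sd"]
            col = []
            for lab in labels:
                mean = means.get(lab, means.get("default"))
                if mean is None:
                    raise ValidationError(
                        f"factor {factor!r}: no mean for class {lab!r}"
                    )
                col.append(rng.normal(mean, sd))
            out[factor] = col
        else:
            raise ValidationError(f"unknown factor type {kind!r} for {factor!r}")
    return pd.DataFrame(out, index=pd.Index(sample_ids, name="sample_id"))


# ---------------------------------------------------------------------------
# presets emulating the qualitative habitat types


def type_I_vagina_like(seed: int = 0, n_subjects: int = 200) -> SyntheticSpec:
    """One strongly dominant class (85% prevalence), single dominant genus;
    low diversity, high silhouette."""
    return SyntheticSpec(
        n_subjects=n_subjects,
        classes=[("Lactobacillus", 0.85), ("Gardnerella", 0.15)],
        dominance=400.0,
        base_concentration=0.08,
        seed=seed,
    )


def type_II_stool_like(seed: int = 0, n_subjects: int = 200) -> SyntheticSpec:
    """Three moderately dominated classes with uneven prevalence."""
    return SyntheticSpec(
        n_subjects=n_subjects,
        classes=[("Bacteroides", 0.6), ("Prevotella", 0.1), ("Ruminococcus", 0.3)],
        dominance=25.0,
        base_concentration=0.4,
        seed=seed,
    )


def type_II_oral_like(seed: int = 0, n_subjects: int = 200) -> SyntheticSpec:
    """Two poorly separated, flat, high-diversity classes (silhouette < 0.2)."""
    return SyntheticSpec(
        n_subjects=n_subjects,
        classes=[("Streptococcus", 0.5), ("Veillonella", 0.5)],
        dominance=4.0,
        base_concentration=1.0,
        seed=seed,
    )


def well_separated(
    seed: int = 0, n_subjects: int = 150, n_classes: int = 3
) -> SyntheticSpec:
    """Strongly dominated, well-separated classes for recovery checks."""
    sigs = ["Bacteroides", "Prevotella", "Ruminococcus", "Lactobacillus",
            "Propionibacterium"][:n_classes]
    weights = np.full(n_classes, 1.0 / n_classes)
    weights[0] += 1.0 - weights.sum()
    return SyntheticSpec(
        n_subjects=n_subjects,
        classes=list(zip(sigs, weights)),
        dominance=500.0,
        base_concentration=0.1,
        seed=seed,
    )


def null_metadata_model(class_names: list[str]) -> dict:
    """Class-independent metadata: no factor is associated with class."""
    return {
        "gender": {
            "type": "categorical",
            "levels": ["female", "male"],
            "probs": {"default": [0.5, 0.5]},
        },
        "location": {
            "type": "categorical",
            "levels": ["StLouis", "Houston"],
            "probs": {"default": [0.5, 0.5]},
        },
        "age": {"type": "continuous", "mean": {"default": 32.0}, "sd": 5.0},
        "bmi": {"type": "continuous", "mean": {"default": 26.0}, "sd": 4.0},
    }


def planted_metadata_model(
    class_names: list[str],
    gender_odds_ratio: float = 5.0,
    age_means: tuple[float, float] = (30.0, 34.0),
    age_sd: float = 5.0,
) -> dict:
    """Metadata with a planted gender and age association.

    The first class's male odds are ``gender_odds_ratio`` times the
    other classes' (whose male probability is 0.5); the first class's
    age mean is ``age_means[0]`` and every other class's ``age_means[1]``.
    """
    p_male = gender_odds_ratio / (gender_odds_ratio + 1.0)
    model = null_metadata_model(class_names)
    model["gender"]["probs"] = {
        class_names[0]: [1.0 - p_male, p_male],
        "default": [0.5, 0.5],
    }
    model["age"]["mean"] = {class_names[0]: age_means[0], "default": age_means[1]}
    model["age"]["sd"] = age_sd
    return model
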