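"""Synthetic community generator with planted co-occurrence structure.

Real soil incubation data behind this kind of study (two soils, a control
and three herbicide doses, five sampling days, three replicates) are not
needed to test the pipeline: what the downstream stages consume is a
taxon x sample table whose taxa fall into correlated blocks.  This module
generates exactly that, with known ground truth, so module detection,
thresholding, stability and comparison all have recovery tests.

The abundance model is a latent Gaussian copula.  Each sample draws one
shared background factor ``g`` and one factor ``f_m`` per planted module;
taxon ``i`` in module ``m`` has latent

    z_i = sqrt(bg) * g + sqrt(rho - bg) * f_m + sqrt(1 - rho) * eps_i

so that within-module pairs correlate at ``rho`` and between-module pairs
at ``bg`` exactly (before the lognormal transform, which attenuates both
slightly but preserves ordering).  Abundances are ``exp(mu_i + sigma*z)``
with a per-taxon lognormal baseline ``mu_i`` — nonnegative, right-skewed,
and with Pearson correlations directly controlled, which is what the
correlation threshold acts on.

Treatment is modelled as *decorrelation*, not abundance scaling: a dose-
dependent fraction of taxa have their latent row redrawn as pure noise,
severing their link to the module factor.  This reproduces the observed
signature of herbicide exposure — fewer edges surviving the threshold —
without changing any taxon's marginal distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    FUNCTION_CATEGORIES,
    OTHERS,
    PREDOMINANT_PHYLA,
    TREATMENT_LEVELS,
    AbundanceTable,
    FunctionTable,
)
from .errors import DesignError

#: Dose-to-severity multipliers: the three doses span two orders of
#: magnitude, modelled as a monotone severity ramp on a linear scale.
TREATMENT_SEVERITY = {"CK": 0.0, "L": 1.0 / 3.0, "M": 2.0 / 3.0, "H": 1.0}

#: sigma of the lognormal transform applied to the latent Gaussians.  Kept
#: moderate so the transform is near-linear and realised Pearson
#: correlations stay close to the latent ones.
LOG_SIGMA = 0.5

#: Default phylum weights: observed node composition of an unperturbed
#: silty-clay soil network (eight predominant phyla plus Others).
DEFAULT_PHYLUM_WEIGHTS: dict = {
    "Acidobacteria": 0.0365,
    "Actinobacteria": 0.1173,
    "Bacteroidetes": 0.0481,
    "Chloroflexi": 0.0288,
    "Gemmatimonadetes": 0.0769,
    "Planctomycetes": 0.1692,
    "Proteobacteria": 0.3769,
    "Verrucomicrobia": 0.1096,
    OTHERS: 0.0367,
}


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the planted-module community generator.

    Defaults emulate the incubation design the pipeline targets: 15
    samples per soil x treatment group (5 sampling days x 3 replicates),
    tight within-module correlation well above the 0.9 network threshold,
    and a strong dose-dependent decorrelation effect.
    """

    n_taxa: int = 120
    n_samples_per_group: int = 15
    n_modules: int = 6
    within_module_corr: float = 0.95
    background_corr: float = 0.1
    phylum_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_WEIGHTS)
    )
    treatment_effect: float = 0.8
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa <= 0 or self.n_samples_per_group <= 0 or self.n_modules < 1:
            raise DesignError("all counts must be positive and n_modules >= 1")
        if not 0.0 <= self.background_corr <= 1.0:
            raise DesignError("background_corr must be in [0, 1]")
        if not 0.0 <= self.within_module_corr <= 1.0:
            raise DesignError("within_module_corr must be in [0, 1]")
        if self.within_module_corr <= self.background_corr:
            raise DesignError("within_module_corr must exceed background_corr")
        if not 0.0 <= self.treatment_effect <= 1.0:
            raise DesignError("treatment_effect must be in [0, 1]")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be nonnegative")
        total = float(sum(self.phylum_weights.values()))
        if abs(total - 1.0) > 1e-9:
            raise DesignError(f"phylum_weights sum to {total}, expected 1")

    def with_seed(self, seed: int) -> "SyntheticDesign":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery tests."""

    true_partition: dict            # taxon id -> module id (1-based)
    broken_edges: set               # frozenset pairs decorrelated by treatment
    linked_function_categories: tuple  # categories coupled to the community

    def partition_labels(self, taxon_ids) -> np.ndarray:
        return np.array([self.true_partition[t] for t in taxon_ids])


def _taxon_ids(n_taxa: int) -> list:
    width = len(str(n_taxa))
    return [f"OTU_{i + 1:0{width}d}" for i in range(n_taxa)]


def _module_assignment(design: SyntheticDesign) -> np.ndarray:
    """Taxa split into near-equal contiguous modules (0-based labels)."""
    sizes = np.full(design.n_modules, design.n_taxa // design.n_modules)
    sizes[: design.n_taxa % design.n_modules] += 1
    return np.repeat(np.arange(design.n_modules), sizes)


def generate_community(
    design: SyntheticDesign, treatment_level: str = "CK"
) -> tuple[AbundanceTable, GroundTruth]:
    """Generate one soil x treatment group with planted module structure.

    The base community (factors, noise, baselines) depends only on
    ``design.seed``, so groups at different treatment levels share their
    unperturbed state and differ exactly by the planted decorrelation:
    a severity-scaled fraction ``treatment_effect * severity(level)`` of
    taxa have their latent rows redrawn as pure noise.
    """
    if treatment_level not in TREATMENT_LEVELS:
        raise DesignError(f"unknown treatment level: {treatment_level!r}")
    n, s = design.n_taxa, design.n_samples_per_group
    rho, bg = design.within_module_corr, design.background_corr
    module_of = _module_assignment(design)

    rng = np.random.default_rng(design.seed)
    factors = rng.standard_normal((design.n_modules, s))
    background = rng.standard_normal(s)
    eps = rng.standard_normal((n, s))
    baseline = rng.normal(0.0, 1.0, size=n)

    z = (
        math.sqrt(bg) * background
        + math.sqrt(rho - bg) * factors[module_of]
        + math.sqrt(1.0 - rho) * eps
    )
    if design.noise_sd > 0:
        extra = rng.standard_normal((n, s))
        z = (z + design.noise_sd * extra) / math.sqrt(1.0 + design.noise_sd**2)

    # dose-dependent decorrelation: redraw latent rows of a random taxon
    # subset as pure noise (marginals preserved, module link severed)
    severity = TREATMENT_SEVERITY[treatment_level]
    n_broken = int(round(design.treatment_effect * severity * n))
    broken_edges: set = set()
    taxa = _taxon_ids(n)
    if n_broken > 0:
        level_idx = TREATMENT_LEVELS.index(treatment_level)
        rng_perturb = np.random.default_rng([design.seed, 100 + level_idx])
        broken = rng_perturb.choice(n, size=n_broken, replace=False)
        z[broken] = rng_perturb.standard_normal((n_broken, s))
        broken_set = set(broken.tolist())
        for m in range(design.n_modules):
            members = np.flatnonzero(module_of == m)
            for i in members:
                for j in members:
                    if i < j and (i in broken_set or j in broken_set):
                        broken_edges.add(frozenset((taxa[i], taxa[j])))

    abundances = np.exp(baseline[:, None] + LOG_SIGMA * z)
    sample_ids = [f"S{treatment_level}_{k + 1:02d}" for k in range(s)]
    values = pd.DataFrame(abundances, index=taxa, columns=sample_ids)

    n_days = 5 if s % 5 == 0 else s
    reps = max(1, s // n_days)
    metadata = pd.DataFrame(
        {
            "soil": "synthetic",
            "treatment": treatment_level,
            "day": [k // reps + 1 for k in range(s)],
            "replicate": [k % reps + 1 for k in range(s)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    rng_link = np.random.default_rng([design.seed, 999])
    linked = tuple(
        sorted(rng_link.choice(FUNCTION_CATEGORIES, size=5, replace=False))
    )
    truth = GroundTruth(
        true_partition={t: int(m) + 1 for t, m in zip(taxa, module_of)},
        broken_edges=broken_edges,
        linked_function_categories=linked,
    )
    return AbundanceTable(values, metadata), truth


def generate_taxonomy(design: SyntheticDesign) -> dict:
    """Assign each taxon a phylum drawn from ``design.phylum_weights``."""
    names = list(design.phylum_weights)
    weights = np.array([design.phylum_weights[p] for p in names], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng([design.seed, 7])
    drawn = rng.choice(len(names), size=design.n_taxa, p=weights)
    return {t: names[k] for t, k in zip(_taxon_ids(design.n_taxa), drawn)}


def _community_score(table: AbundanceTable) -> np.ndarray:
    """First principal coordinate of the Bray-Curtis distances, standardised.

    One scalar per sample summarising where it sits along the dominant
    compositional gradient; used as the signal that linked function
    categories couple to.
    """
    from .comparison import bray_curtis

    d = bray_curtis(table).to_numpy()
    n = d.shape[0]
    # classical MDS: double-centre the squared distances
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    axis = vecs[:, -1] * math.sqrt(max(vals[-1], 0.0))
    sd = axis.std()
    if sd == 0:
        return np.zeros(n)
    return (axis - axis.mean()) / sd


def generate_function_table(
    table: AbundanceTable,
    truth: GroundTruth,
    coupling: float = 0.8,
    seed: int = 0,
) -> FunctionTable:
    """Function-category table partially coupled to community composition.

    Linked categories are ``coupling * score + (1 - coupling) * noise``
    where ``score`` is the sample's coordinate on the dominant Bray-Curtis
    gradient; unlinked categories are pure noise.  Each category row is
    affinely rescaled to positive values (affine maps leave its pairwise
    Euclidean distances, and hence Mantel correlations, proportional).
    """
    if not 0.0 <= coupling <= 1.0:
        raise DesignError("coupling must be in [0, 1]")
    rng = np.random.default_rng([seed, 13])
    score = _community_score(table)
    n_samples = len(score)
    rows = {}
    for category in FUNCTION_CATEGORIES:
        noise = rng.standard_normal(n_samples)
        if category in truth.linked_function_categories:
            signal = coupling * score + (1.0 - coupling) * noise
        else:
            signal = noise
        scale = rng.uniform(0.5, 2.0)
        row = scale * signal
        rows[category] = row - row.min() + 0.01
    values = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    values.columns = table.sample_ids
    return FunctionTable(values.loc[list(FUNCTION_CATEGORIES)])
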