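"""Synthetic expression cohorts with planted subtype structure.

Real consensus-subtyping studies train on large access-controlled cohorts
(bead-array, Affymetrix, RNA-seq).  This module generates cohorts with the
same statistical shape — k latent subtypes, disjoint blocks of
subtype-elevated marker genes, Gaussian noise on the log scale, and an
optional fraction of "noise" samples carrying no subtype signal — so that
every stage of the pipeline is testable against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

NONE_LABEL = "NONE"


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a planted-subtype cohort.

    All expression values are on a log2-like scale.  Each subtype owns a
    disjoint block of ``markers_per_subtype`` genes whose mean is shifted up
    by ``effect`` in that subtype's samples.  ``frac_noise_samples`` of the
    samples belong to no subtype (truth label ``NONE``).
    """

    n_samples: int = 300
    n_genes: int = 2000
    k_subtypes: int = 4
    markers_per_subtype: int = 50
    effect: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 0.0
    frac_noise_samples: float = 0.0
    mixing_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_subtypes * self.markers_per_subtype > self.n_genes:
            raise ValueError(
                f"{self.k_subtypes} subtypes x {self.markers_per_subtype} markers "
                f"exceed {self.n_genes} genes"
            )
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0 <= self.frac_noise_samples < 1:
            raise ValueError("frac_noise_samples must be in [0, 1)")
        if self.mixing_proportions is not None:
            if len(self.mixing_proportions) != self.k_subtypes:
                raise ValueError("mixing_proportions length must equal k_subtypes")
            if abs(sum(self.mixing_proportions) - 1.0) > 1e-9:
                raise ValueError("mixing_proportions must sum to 1")

    @property
    def proportions(self) -> np.ndarray:
        if self.mixing_proportions is not None:
            return np.asarray(self.mixing_proportions, dtype=float)
        return np.full(self.k_subtypes, 1.0 / self.k_subtypes)


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate a cohort; returns (matrix, truth) with truth sample -> subtype or NONE.

    Baseline values are Normal(baseline_mean + gene offset, noise_sd), where
    each gene's offset is Normal(0, baseline_sd); each subtype's samples get
    ``+effect`` on that subtype's marker block.  Same spec + seed is
    byte-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    n, g, k = spec.n_samples, spec.n_genes, spec.k_subtypes

    n_noise = int(round(spec.frac_noise_samples * n))
    n_typed = n - n_noise
    # deterministic rounded allocation of typed samples over subtypes
    counts = np.floor(spec.proportions * n_typed).astype(int)
    remainder = n_typed - counts.sum()
    order = np.argsort(-(spec.proportions * n_typed - counts))
    counts[order[:remainder]] += 1
    labels = np.concatenate(
        [np.repeat(i, c) for i, c in enumerate(counts)] + [np.repeat(-1, n_noise)]
    )
    rng.shuffle(labels)

    gene_offsets = rng.normal(0.0, spec.baseline_sd, size=g)
    X = rng.normal(0.0, 1.0, size=(g, n)) * spec.noise_sd
    X += spec.baseline_mean + gene_offsets[:, None]
    for i in range(k):
        block = slice(i * spec.markers_per_subtype, (i + 1) * spec.markers_per_subtype)
        X[block, labels == i] += spec.effect

    gene_ids = [f"G{j:05d}" for j in range(g)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    matrix = ExpressionMatrix(pd.DataFrame(X, index=gene_ids, columns=sample_ids))
    truth = pd.Series(
        [NONE_LABEL if l < 0 else f"K{l + 1}" for l in labels],
        index=sample_ids,
        name="subtype",
    )
    return matrix, truth


def generate_system_fixtures(
    n_systems: int,
    n_samples: int = 120,
    k_latent: int = 4,
    agreement: float = 1.0,
    seed: int = 0,
    subtypes_per_system: list[int] | None = None,
) -> tuple[list["SubtypeSystem"], pd.Series]:
    """Subtype systems derived from a common latent partition.

    Each system copies the latent partition and then corrupts each sample's
    label independently with probability ``1 - agreement`` (relabelling
    uniformly at random over that system's label set).  ``agreement=1`` gives
    identical systems; ``agreement=0`` gives independent random partitions.
    Unit-test input for the subtype-network stage without running the six
    subtyping methods.
    """
    from .methods import SubtypeSystem  # local import to avoid a cycle

    if not 0 <= agreement <= 1:
        raise ValueError("agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    latent = rng.integers(0, k_latent, size=n_samples)
    method_ids = [chr(ord("A") + i) for i in range(n_systems)]
    systems = []
    for mi, method_id in enumerate(method_ids):
        k_sys = subtypes_per_system[mi] if subtypes_per_system else k_latent
        labels = latent.copy() % k_sys
        corrupt = rng.random(n_samples) >= agreement
        labels[corrupt] = rng.integers(0, k_sys, size=int(corrupt.sum()))
        label_map = {s: f"{method_id}{l + 1}" for s, l in zip(sample_ids, labels)}
        systems.append(SubtypeSystem(method_id=method_id, labels=label_map))
    truth = pd.Series([f"K{l + 1}" for l in latent], index=sample_ids, name="latent")
    return systems, truth
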