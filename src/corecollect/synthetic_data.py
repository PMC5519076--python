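"""Synthetic genotype collections with known founder structure.

Emulates a germplasm collection of ``n_founders`` distinct prototype lines,
each deposited ``dups_per_founder`` times (accession duplication is the rule,
not the exception, in genebanks).  Founder genotypes are drawn per marker
under Hardy-Weinberg proportions with a reference-allele frequency sampled
from a Beta distribution (a U-shaped Beta(0.8, 0.8) by default, mimicking
the allele-frequency spectrum of SNP arrays).  Copies are then perturbed by
per-call genotyping error (``mutation_rate`` resamples the call, producing
near-duplicates) and per-call dropout (``missing_rate``), both i.i.d. over
the final matrix.

What it does not emulate: linkage disequilibrium between markers, pedigree
relatedness between founders, and population-specific missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["SyntheticSpec", "generate"]

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Parameters of one simulated collection.

    ``maf_dist`` is the (a, b) shape pair of the Beta distribution the
    per-marker reference-allele frequency is drawn from.
    ``multiallelic_fraction`` markers get a third allele (frequencies from a
    flat Dirichlet) to exercise genotype-class logic beyond biallelic.
    """

    n_founders: int = 25
    dups_per_founder: int = 20
    n_markers: int = 2000
    maf_dist: tuple[float, float] = (0.8, 0.8)
    missing_rate: float = 0.0
    mutation_rate: float = 0.0
    multiallelic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_founders, self.dups_per_founder, self.n_markers) < 1:
            raise ValueError("n_founders, dups_per_founder and n_markers must be >= 1")
        for name in ("missing_rate", "mutation_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0.0 <= self.multiallelic_fraction <= 1.0):
            raise ValueError("multiallelic_fraction must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_founders * self.dups_per_founder


def _draw_genotypes(rng, freqs: np.ndarray, symbols: np.ndarray, size: int) -> np.ndarray:
    """Diploid HWE draw: two independent alleles per sample, sorted call."""
    picks = rng.choice(len(symbols), size=(size, 2), p=freqs)
    a = symbols[np.sort(picks, axis=1)]
    return np.array(["".join(pair) for pair in a], dtype=object)


def generate(spec: SyntheticSpec) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate a collection; returns the matrix and per-sample founder labels.

    Deterministic under ``spec.seed``.  Sample IDs are ``F<f>_D<c>`` so the
    truth partition is also readable from the IDs; marker IDs are ``M<i>``.
    """
    rng = np.random.default_rng(spec.seed)
    nf, dups, m = spec.n_founders, spec.dups_per_founder, spec.n_markers
    n = nf * dups
    calls = np.empty((nf, m), dtype=object)
    marker_symbols: list[np.ndarray] = []
    marker_freqs: list[np.ndarray] = []
    p_ref = rng.beta(*spec.maf_dist, size=m)
    tri = rng.random(m) < spec.multiallelic_fraction
    for i in range(m):
        k = 3 if tri[i] else 2
        symbols = rng.choice(_NUCLEOTIDES, size=k, replace=False)
        symbols = np.sort(symbols)
        if k == 2:
            freqs = np.array([p_ref[i], 1.0 - p_ref[i]])
        else:
            freqs = rng.dirichlet(np.ones(k))
            p_ref[i] = freqs[0]
        marker_symbols.append(symbols)
        marker_freqs.append(freqs)
        calls[:, i] = _draw_genotypes(rng, freqs, symbols, nf)
    G = np.repeat(calls, dups, axis=0)
    labels = np.repeat(np.arange(nf), dups)
    if spec.mutation_rate > 0.0:
        mut = rng.random((n, m)) < spec.mutation_rate
        for i in np.where(mut.any(axis=0))[0]:
            rows = np.where(mut[:, i])[0]
            G[rows, i] = _draw_genotypes(rng, marker_freqs[i], marker_symbols[i], len(rows))
    if spec.missing_rate > 0.0:
        drop = rng.random((n, m)) < spec.missing_rate
        G[drop] = MISSING
    sample_ids = [f"F{f:04d}_D{c:02d}" for f in range(nf) for c in range(dups)]
    marker_ids = [f"M{i:05d}" for i in range(m)]
    return GenotypeMatrix(sample_ids, marker_ids, G), labels
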