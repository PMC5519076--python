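"""Evaluation statistics for sample subsets.

For any subset of samples (a candidate core, a random baseline, the whole
collection) this module computes the statistics used to judge core quality:

* ``CV``  — genetic coverage: mean over markers of the fraction of
  entire-collection genotype classes present in the subset, as a percent;
* ``SH``  — Shannon diversity index over per-marker reference-allele
  frequencies of the subset: ``-sum_i p_i ln p_i``;
* ``MR``  — modified Rogers distance between two samples,
  ``sqrt( (1/2m) sum_i sum_j (p_xij - p_yij)^2 )`` over pairwise-complete
  markers, with per-sample allele frequencies p_xij in {0, 1/2, 1} for
  diploids; mean and minimum over all subset pairs summarise redundancy;
* the reference-allele frequency spectrum, for checking that a core
  preserves the allele-frequency distribution of the entire collection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix
from .scoring import CoverageState, MarkerClassTable

__all__ = [
    "AlleleFrequencyTable",
    "CoreMetrics",
    "build_allele_table",
    "cv",
    "shannon",
    "modified_rogers",
    "evaluate_core",
    "allele_frequency_spectrum",
    "spectrum_max_difference",
]


def call_alleles(code: str) -> list[str]:
    """Split a canonical genotype-class code into its allele symbols.

    ``a/b`` styles split on the separator, two-character nucleotide calls
    split characterwise, and any other single token is treated as a
    homozygote for that token.
    """
    if "/" in code:
        return code.split("/")
    if len(code) == 2:
        return list(code)
    return [code, code]


@dataclass
class AlleleFrequencyTable:
    """Per-sample allele dosages and per-marker reference alleles.

    ``ref_dosage[x, i]`` is sample x's relative frequency of the reference
    allele at marker i (0, 0.5 or 1 for diploids; NaN when missing).
    ``dosage[x, s]`` covers every allele slot (``allele_offsets`` indexes
    slots per marker) and supports multi-allelic markers.
    """

    ref_allele: list[str]             # per marker
    alleles: list[list[str]]          # per marker, allele symbols in slot order
    allele_offsets: np.ndarray        # (m + 1,)
    dosage: np.ndarray                # (n_samples, total_slots), NaN if missing
    ref_dosage: np.ndarray            # (n_samples, m), NaN if missing

    @property
    def n_markers(self) -> int:
        return len(self.ref_allele)


def build_allele_table(G: GenotypeMatrix, ref_alleles: list[str] | None = None) -> AlleleFrequencyTable:
    """Decompose genotype classes into allele dosages.

    The reference allele is taken from ``ref_alleles`` (or the matrix's own
    VCF-derived metadata) when given; otherwise the major allele of the
    entire collection at each marker (ties broken lexicographically).
    """
    if ref_alleles is None:
        ref_alleles = G.ref_alleles
    n, m = G.n_samples, G.n_markers
    alleles_per_marker: list[list[str]] = []
    offsets = np.zeros(m + 1, dtype=np.int64)
    ref: list[str] = []
    marker_allele_dosage: list[np.ndarray] = []
    for i in range(m):
        col = G.calls[:, i]
        symbols: dict[str, int] = {}
        parsed: list[list[str] | None] = []
        for c in col:
            if c == MISSING:
                parsed.append(None)
                continue
            al = call_alleles(c)
            for a in al:
                symbols.setdefault(a, len(symbols))
            parsed.append(al)
        order = sorted(symbols)
        alleles_per_marker.append(order)
        offsets[i + 1] = offsets[i] + len(order)
        dos = np.full((n, len(order)), np.nan)
        index = {a: k for k, a in enumerate(order)}
        for x, al in enumerate(parsed):
            if al is None:
                continue
            dos[x] = 0.0
            for a in al:
                dos[x, index[a]] += 1.0 / len(al)
        marker_allele_dosage.append(dos)
        if ref_alleles is not None:
            ref.append(ref_alleles[i])
        elif order:
            totals = np.nansum(dos, axis=0)
            ref.append(order[int(np.argmax(totals))] if len(order) else "")
        else:
            ref.append("")
    dosage = (
        np.concatenate(marker_allele_dosage, axis=1)
        if int(offsets[-1]) > 0
        else np.zeros((n, 0))
    )
    ref_dosage = np.full((n, m), np.nan)
    for i in range(m):
        order = alleles_per_marker[i]
        if ref[i] in order:
            ref_dosage[:, i] = dosage[:, offsets[i] + order.index(ref[i])]
        elif order:
            # reference allele absent from the data: dosage 0 where called
            called = ~np.isnan(dosage[:, offsets[i]])
            ref_dosage[called, i] = 0.0
    return AlleleFrequencyTable(
        ref_allele=ref,
        alleles=alleles_per_marker,
        allele_offsets=offsets,
        dosage=dosage,
        ref_dosage=ref_dosage,
    )


@dataclass
class CoreMetrics:
    """One row of a core-quality report (columns: n, MR, min MR, SH, CV)."""

    n_samples: int
    cv_percent: float
    sh: float
    mr_mean: float | None
    mr_min: float | None

    def as_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "mr_mean": self.mr_mean,
            "mr_min": self.mr_min,
            "sh": self.sh,
            "cv_percent": self.cv_percent,
        }


def _subset_indices(G: GenotypeMatrix, subset) -> list[int]:
    return [s if isinstance(s, (int, np.integer)) else G.sample_index(s) for s in subset]


def cv(subset, G: GenotypeMatrix, T: MarkerClassTable) -> float:
    """Coverage of entire-collection genotype classes by the subset, percent."""
    idx = _subset_indices(G, subset)
    if not idx:
        return 0.0
    return CoverageState.from_subset(T, idx).cv_percent(T)


def _subset_ref_freqs(A: AlleleFrequencyTable, idx) -> np.ndarray:
    """Per-marker reference-allele frequency within a subset (NaN if uncalled)."""
    sub = A.ref_dosage[idx]
    called = (~np.isnan(sub)).sum(axis=0)
    total = np.nansum(sub, axis=0)
    return np.where(called > 0, total / np.maximum(called, 1), np.nan)


def shannon(subset, G: GenotypeMatrix, A: AlleleFrequencyTable) -> float:
    """Shannon index -sum_i p_i ln p_i over subset reference-allele freqs.

    p_i is recomputed within the subset from non-missing calls; markers the
    subset never calls, and p_i = 0 terms, contribute 0.
    """
    idx = _subset_indices(G, subset)
    if not idx:
        raise ValueError("empty subset")
    p = _subset_ref_freqs(A, idx)
    p = p[~np.isnan(p)]
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def modified_rogers(x, y, A: AlleleFrequencyTable, G: GenotypeMatrix | None = None) -> float:
    """Modified Rogers distance between two samples, in [0, 1].

    Uses pairwise-complete markers only, rescaling the 1/(2m) normaliser to
    the number of shared markers; raises if the samples share none.
    """
    if G is not None:
        x, y = _subset_indices(G, [x, y])
    dx, dy = A.dosage[x], A.dosage[y]
    diff = dx - dy
    marker_ok = np.zeros(A.n_markers, dtype=bool)
    off = A.allele_offsets
    valid_slot = ~(np.isnan(dx) | np.isnan(dy))
    for i in range(A.n_markers):
        lo, hi = off[i], off[i + 1]
        marker_ok[i] = hi > lo and bool(valid_slot[lo:hi].all())
    m_shared = int(marker_ok.sum())
    if m_shared == 0:
        raise ValueError("samples share no pairwise-complete marker; MR undefined")
    slot_ok = np.zeros(A.dosage.shape[1], dtype=bool)
    for i in np.where(marker_ok)[0]:
        slot_ok[off[i]:off[i + 1]] = True
    total = float(np.nansum(diff[slot_ok] ** 2))
    return float(np.sqrt(total / (2.0 * m_shared)))


def evaluate_core(
    subset, G: GenotypeMatrix, T: MarkerClassTable, A: AlleleFrequencyTable
) -> CoreMetrics:
    """CV, SH and pairwise-MR summary for a subset (MR undefined for n<2)."""
    idx = _subset_indices(G, subset)
    if not idx:
        raise ValueError("empty subset")
    cv_val = cv(idx, G, T)
    sh_val = shannon(idx, G, A)
    mr_mean = mr_min = None
    if len(idx) >= 2:
        dists = [modified_rogers(a, b, A) for a, b in itertools.combinations(idx, 2)]
        mr_mean = float(np.mean(dists))
        mr_min = float(np.min(dists))
    return CoreMetrics(
        n_samples=len(idx), cv_percent=cv_val, sh=sh_val, mr_mean=mr_mean, mr_min=mr_min
    )


def allele_frequency_spectrum(
    subset, G: GenotypeMatrix, A: AlleleFrequencyTable, bin_width: float = 0.05
):
    """Histogram of per-marker reference-allele frequencies within a subset.

    Returns ``(counts, bin_edges)`` over [0, 1]; markers with no non-missing
    call in the subset are excluded.
    """
    if not (0.0 < bin_width <= 1.0):
        raise ValueError("bin_width must lie in (0, 1]")
    idx = _subset_indices(G, subset)
    p = _subset_ref_freqs(A, idx)
    p = p[~np.isnan(p)]
    nbins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(nbins + 1) * bin_width, 1.0)
    counts, _ = np.histogram(p, bins=edges)
    return counts, edges


def spectrum_max_difference(
    subset_a, subset_b, G: GenotypeMatrix, A: AlleleFrequencyTable, bin_width: float = 0.05
) -> float:
    """Max absolute difference between two normalised allele-frequency spectra."""
    ca, _ = allele_frequency_spectrum(subset_a, G, A, bin_width)
    cb, _ = allele_frequency_spectrum(subset_b, G, A, bin_width)
    fa = ca / ca.sum() if ca.sum() else ca.astype(float)
    fb = cb / cb.sum() if cb.sum() else cb.astype(float)
    return float(np.max(np.abs(fa - fb)))
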