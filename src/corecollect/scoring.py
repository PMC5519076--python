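"""Genotype-class frequency tables and the coverage / diversity scores.

The greedy selector ranks candidate samples by a *coverage score*

    C_j = (1 / n(N_j)) * sum_{i in N_j} f_{i, g_ij}

where ``N_j`` is the set of markers at which sample ``j`` is non-missing,
``g_ij`` its genotype class at marker ``i``, and ``f_{i,c}`` the relative
frequency of class ``c`` at marker ``i`` in the entire collection (computed
over non-missing calls).  After the first pick, frequency terms belonging to
(marker, class) pairs already covered by the growing core are zeroed, so
C_j measures only what the candidate would newly contribute; the
denominator n(N_j) depends solely on missingness and is never reduced.

Ties in C_j are broken by the *diversity score*

    D_j = (1 / n(N_j)) * sum_{i in N_j} (f_{i, g_ij} - C_j)^2

the mean squared deviation of the same (masked) frequency terms around C_j;
the sample with minimum D_j — the one carrying the most uniformly common
alleles — is preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "MarkerClassTable",
    "CoverageState",
    "SampleScore",
    "build_class_table",
    "coverage_score",
    "coverage_scores",
    "diversity_score",
]


@dataclass
class MarkerClassTable:
    """Per-marker genotype classes and their entire-collection frequencies.

    Classes at marker ``i`` occupy the flat slot range
    ``offsets[i]:offsets[i+1]``; ``codes[j, i]`` is the slot of sample j's
    class (``n_slots`` = a dummy slot when the call is missing, with
    ``freq_flat`` 0 there).  ``ge[i] = |classes[i]|`` is the
    entire-collection class count; ``informative[i]`` is False iff every
    call at marker i is missing.
    """

    classes: list[list[str]]          # per marker, class codes in slot order
    freq_flat: np.ndarray             # frequency per flat slot (+ trailing dummy 0)
    offsets: np.ndarray               # (m + 1,) slot range per marker
    codes: np.ndarray                 # (n_samples, m) flat slot, n_slots if missing
    ge: np.ndarray                    # (m,) classes per marker (0 if uninformative)
    informative: np.ndarray           # (m,) bool
    nonmissing_counts: np.ndarray     # (n_samples,) = n(N_j) per sample

    @property
    def n_slots(self) -> int:
        return int(self.offsets[-1])

    @property
    def n_markers(self) -> int:
        return len(self.classes)

    def freq(self, marker: int, cls: str) -> float:
        """Relative frequency of class ``cls`` at ``marker``."""
        i = self.classes[marker].index(cls)
        return float(self.freq_flat[self.offsets[marker] + i])

    def marker_of_slot(self) -> np.ndarray:
        out = np.empty(self.n_slots, dtype=np.int64)
        for i in range(self.n_markers):
            out[self.offsets[i]:self.offsets[i + 1]] = i
        return out


def build_class_table(G: GenotypeMatrix) -> MarkerClassTable:
    """Tabulate distinct genotype classes and frequencies per marker.

    Frequencies use the non-missing call count at the marker as denominator;
    all-missing markers are flagged uninformative (never fatal).
    """
    if G.n_samples == 0 or G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    n, m = G.n_samples, G.n_markers
    classes: list[list[str]] = []
    offsets = np.zeros(m + 1, dtype=np.int64)
    codes = np.empty((n, m), dtype=np.int64)
    freqs: list[np.ndarray] = []
    ge = np.zeros(m, dtype=np.int64)
    informative = np.zeros(m, dtype=bool)
    for i in range(m):
        col = G.calls[:, i]
        nonmiss = col != MISSING
        uniq, inv, counts = np.unique(col[nonmiss].astype(str), return_inverse=True, return_counts=True)
        cls = list(uniq)
        classes.append(cls)
        ge[i] = len(cls)
        informative[i] = len(cls) > 0
        base = offsets[i]
        offsets[i + 1] = base + len(cls)
        codes[:, i] = -1
        codes[nonmiss, i] = base + inv
        freqs.append(counts / counts.sum() if len(cls) else np.empty(0))
    n_slots = int(offsets[-1])
    freq_flat = np.concatenate([*freqs, [0.0]]) if freqs else np.zeros(1)
    codes[codes < 0] = n_slots  # missing -> dummy slot
    nonmissing = (G.calls != MISSING).sum(axis=1).astype(np.int64)
    return MarkerClassTable(
        classes=classes,
        freq_flat=freq_flat,
        offsets=offsets,
        codes=codes,
        ge=ge,
        informative=informative,
        nonmissing_counts=nonmissing,
    )


@dataclass
class CoverageState:
    """Which (marker, class) pairs the growing core already carries.

    ``covered`` is a flat boolean over class slots (+ a trailing dummy that
    stays False).  Flags are monotone within one selection run: once a class
    is covered it is never reset.
    """

    covered: np.ndarray  # (n_slots + 1,) bool
    _marker_of_slot: np.ndarray = field(repr=False)
    _offsets: np.ndarray = field(repr=False)

    @classmethod
    def empty(cls, T: MarkerClassTable) -> "CoverageState":
        return cls(
            covered=np.zeros(T.n_slots + 1, dtype=bool),
            _marker_of_slot=T.marker_of_slot(),
            _offsets=T.offsets,
        )

    @classmethod
    def from_subset(cls, T: MarkerClassTable, sample_indices) -> "CoverageState":
        state = cls.empty(T)
        for j in sample_indices:
            state.cover_sample(T, j)
        return state

    def cover_sample(self, T: MarkerClassTable, j: int) -> None:
        """Mark every class carried by sample ``j`` as covered."""
        self.covered[T.codes[j]] = True
        self.covered[-1] = False  # dummy slot never counts

    def gc(self) -> np.ndarray:
        """Per-marker covered-class count GC_i."""
        flags = self.covered[:-1].astype(np.int64)
        m = len(self._offsets) - 1
        out = np.zeros(m, dtype=np.int64)
        np.add.at(out, self._marker_of_slot, flags)
        return out

    def cv_percent(self, T: MarkerClassTable) -> float:
        """Coverage CV = 100/m' * sum_i GC_i/GE_i over informative markers."""
        inf = T.informative
        if not inf.any():
            return 0.0
        return float(100.0 * np.mean(self.gc()[inf] / T.ge[inf]))


@dataclass
class SampleScore:
    sample_id: str
    c_score: float
    d_score: float | None = None


def _masked_freqs(T: MarkerClassTable, S: CoverageState) -> np.ndarray:
    # freq_flat and covered both carry the trailing dummy slot
    f = T.freq_flat.copy()
    f[S.covered] = 0.0
    return f


def coverage_scores(T: MarkerClassTable, S: CoverageState, sample_indices) -> np.ndarray:
    """Vectorised C_j for several samples under coverage mask ``S``."""
    idx = np.asarray(sample_indices, dtype=np.int64)
    f_eff = _masked_freqs(T, S)
    totals = f_eff[T.codes[idx]].sum(axis=1)
    denom = T.nonmissing_counts[idx]
    out = np.zeros(len(idx), dtype=float)
    ok = denom > 0
    out[ok] = totals[ok] / denom[ok]
    if not ok.all():
        warnings.warn("sample(s) with no non-missing call scored 0", stacklevel=2)
    return out


def coverage_score(
    G: GenotypeMatrix, T: MarkerClassTable, S: CoverageState, j: int
) -> float:
    """C_j for one sample: mean not-yet-covered class frequency over N_j."""
    return float(coverage_scores(T, S, [j])[0])


def diversity_score(
    G: GenotypeMatrix,
    T: MarkerClassTable,
    S: CoverageState,
    j: int,
    c_j: float,
) -> float:
    """D_j: mean squared deviation of sample j's masked f-terms around C_j.

    Uses the same coverage masking as the C_j it is paired with, so the
    tie-break measures spread around the score actually compared.
    """
    code_row = T.codes[j]
    valid = code_row < T.n_slots
    if not valid.any():
        warnings.warn(f"sample index {j} has no non-missing call; D=0", stacklevel=2)
        return 0.0
    f_eff = _masked_freqs(T, S)
    terms = f_eff[code_row[valid]]
    return float(np.mean((terms - c_j) ** 2))
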