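"""Genotype-matrix input/output.

Reads sample x marker grids of genotype calls from a delimited text dialect
or from VCF, normalising every call into a canonical *genotype-class* code.
A genotype class is a distinct genotype value observed at a marker (``AA``,
``AG``, ``0/1`` ...); missing or ambiguous calls are mapped to a single
missing sentinel and are never classes.

Canonicalisation rules
----------------------
* calls containing ``/`` or ``|`` are split into alleles; alleles are sorted
  (numerically where possible) and re-joined with ``/`` — ``0/1``, ``1/0``
  and ``0|1`` are one class;
* two-character nucleotide calls are sorted characterwise — ``AG`` and
  ``GA`` are one class;
* any other token (``A``, ``0``, ``2``, a microsatellite length ...) is kept
  verbatim;
* anything in the missing-code set, and any genotype with a missing allele
  (``./.``, ``0/.``), becomes :data:`MISSING`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "DEFAULT_MISSING_CODES",
    "GenotypeMatrix",
    "normalize_call",
    "read_matrix",
    "write_matrix",
    "read_vcf",
    "write_core_list",
    "write_trace",
]

#: canonical in-memory code for a missing / ambiguous genotype call
MISSING = ""

#: cell values recognised as missing in the delimited matrix dialect
DEFAULT_MISSING_CODES = frozenset({"NA", "--", "NN", "./.", ".", ""})

#: string written for missing cells when emitting the matrix dialect
MISSING_OUT = "NA"


def _allele_sort_key(allele: str):
    # numeric alleles (VCF indices) sort numerically, others lexically
    return (0, int(allele), "") if allele.isdigit() else (1, 0, allele)


def normalize_call(raw: str, missing_codes=DEFAULT_MISSING_CODES) -> str:
    """Map a raw genotype string to its canonical class code (or MISSING)."""
    s = raw.strip()
    if s in missing_codes:
        return MISSING
    if "/" in s or "|" in s:
        alleles = s.replace("|", "/").split("/")
        if any(a in (".", "") for a in alleles):
            return MISSING  # half-calls are ambiguous
        return "/".join(sorted(alleles, key=_allele_sort_key))
    if len(s) == 2:
        return "".join(sorted(s))
    return s


@dataclass
class GenotypeMatrix:
    """An n_samples x m grid of canonical genotype-class codes.

    ``calls`` holds one class code (or :data:`MISSING`) per cell.
    ``ref_alleles`` is optional per-marker reference-allele symbol metadata
    (populated by :func:`read_vcf`, where REF is allele ``"0"``).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # dtype=object, shape (n_samples, m)
    ref_alleles: list[str] | None = None
    missing_counts: np.ndarray = field(init=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=object)
        n, m = len(self.sample_ids), len(self.marker_ids)
        if self.calls.shape != (n, m):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n} samples, {m} markers)"
            )
        for name, ids in (("sample", self.sample_ids), ("marker", self.marker_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} ID: {i!r}")
                seen.add(i)
        self.missing_counts = (self.calls == MISSING).sum(axis=1)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample ID: {sample_id!r}") from None


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_matrix(
    path: str | os.PathLike,
    delimiter: str | None = None,
    missing_codes=DEFAULT_MISSING_CODES,
) -> GenotypeMatrix:
    """Read the delimited matrix dialect.

    First row: marker IDs (the leading cell, if any, is ignored).  First
    column: sample IDs.  ``delimiter=None`` auto-detects tab vs comma.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = delimiter or _sniff_delimiter(lines[0])
    header = lines[0].split(delim)
    # header may or may not carry a corner label for the sample-ID column
    body = [ln.split(delim) for ln in lines[1:]]
    if not body:
        raise ValueError(f"{path}: no sample rows")
    ncol = len(body[0])
    if len(header) == ncol:
        marker_ids = header[1:]
    elif len(header) == ncol - 1:
        marker_ids = header
    else:
        raise ValueError(
            f"{path}: header has {len(header)} fields but row 1 has {ncol}"
        )
    sample_ids, rows = [], []
    for r, fields in enumerate(body, start=1):
        if len(fields) != ncol:
            raise ValueError(f"{path}: ragged row {r} ({len(fields)} != {ncol} fields)")
        sample_ids.append(fields[0])
        rows.append([normalize_call(c, missing_codes) for c in fields[1:]])
    calls = np.array(rows, dtype=object)
    return GenotypeMatrix(sample_ids, marker_ids, calls)


def write_matrix(G: GenotypeMatrix, path: str | os.PathLike, delimiter: str = "\t") -> None:
    """Write the matrix dialect (missing cells as ``NA``)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(["sample", *G.marker_ids]) + "\n")
        for j, sid in enumerate(G.sample_ids):
            row = [c if c != MISSING else MISSING_OUT for c in G.calls[j]]
            fh.write(delimiter.join([sid, *row]) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read genotypes from a VCF; each site becomes one marker.

    GT fields are mapped to unordered allele-index multisets ("0/1", "1|0"
    and "0/1" are one class); any genotype containing a missing allele maps
    to the missing sentinel.  Multi-allelic sites yield one class per
    observed allele pair.  REF is recorded as allele symbol "0".
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{path}: VCF has zero samples")
    marker_ids, columns = [], []
    for var in vcf:
        if "GT" not in (var.FORMAT or ["GT"]):
            raise ValueError(f"{path}: site {var.CHROM}:{var.POS} lacks a GT field")
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        col = []
        for gt in var.genotypes:  # [a0, a1, ..., phased_flag]
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                col.append(MISSING)
            else:
                col.append("/".join(str(a) for a in sorted(alleles)))
        marker_ids.append(mid)
        columns.append(col)
    vcf.close()
    if not marker_ids:
        raise ValueError(f"{path}: VCF has zero sites")
    calls = np.array(columns, dtype=object).T
    return GenotypeMatrix(sample_ids, marker_ids, calls, ref_alleles=["0"] * len(marker_ids))


def write_core_list(result, path: str | os.PathLike) -> None:
    """Write the selected core: one sample ID per line, in selection order."""
    if not result.core_ids:
        raise ValueError("empty selection result")
    with open(path, "w", encoding="utf-8") as fh:
        for sid in result.core_ids:
            fh.write(sid + "\n")


def read_core_list(path: str | os.PathLike) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_trace(result, path: str | os.PathLike) -> None:
    """Write the per-step selection trace as a CSV table."""
    import pandas as pd

    if not result.trace:
        raise ValueError("empty selection result")
    df = pd.DataFrame(
        {
            "step": [t.step for t in result.trace],
            "sample_id": [t.sample_id for t in result.trace],
            "coverage_score": [t.coverage_score for t in result.trace],
            "diversity_score": [t.diversity_score for t in result.trace],
            "cumulative_cv_percent": [t.cumulative_cv_percent for t in result.trace],
            "n_removed_duplicates": [len(t.removed_duplicates) for t in result.trace],
        }
    )
    df.to_csv(path, index=False)
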