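"""Readers and writers for founder panels, pool-seq time series and result
tables.

Formats (all plain text, 1-based positions in files):

- founder TSV: optional ``#region_length=<bp>`` comment, a header row of
  basepair positions, then one row of tab-separated 0/1 alleles per founder
  haplotype;
- founder FASTA-like: a leading ``;region_length=...;positions=...`` comment
  line, then one ``>founder_<i>`` record per founder whose sequence is a 0/1
  string;
- sync: ``chrom  pos  ref  A:T:C:G:N:del ...`` with one count sextet per
  sample; the derived allele is written as base T and the ancestral as base
  A, one sample column per (generation, replicate) pair;
- long TSV: columns generation, replicate, position, count, coverage,
  frequency (count/coverage columns empty for infinite-coverage data).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import FounderPanel, TrajectoryData

__all__ = [
    "read_founders",
    "write_founders",
    "read_founders_fasta",
    "write_founders_fasta",
    "read_sync",
    "write_sync",
    "read_long_tsv",
    "write_long_tsv",
    "write_results",
]

_BASES = ("A", "T", "C", "G", "N", "del")
DERIVED_BASE = "T"
ANCESTRAL_BASE = "A"


# ---------------------------------------------------------------------------
# founder panels
# ---------------------------------------------------------------------------


def write_founders(panel: FounderPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#region_length={panel.region_length}\n")
        fh.write("\t".join(str(p) for p in panel.positions) + "\n")
        for row in panel.haplotypes:
            fh.write("\t".join(str(int(a)) for a in row) + "\n")


def read_founders(path) -> FounderPanel:
    lines = Path(path).read_text().splitlines()
    region_length = None
    body = []
    for ln in lines:
        if ln.startswith("#"):
            if ln.startswith("#region_length="):
                region_length = int(ln.split("=", 1)[1])
            continue
        if ln.strip():
            body.append(ln)
    if not body:
        raise ValueError(f"{path}: no header row of positions")
    positions = np.array([int(x) for x in body[0].split("\t")])
    rows = []
    for i, ln in enumerate(body[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != positions.size:
            raise ValueError(f"{path}: row {i} has {len(fields)} fields, expected {positions.size}")
        if any(f not in ("0", "1") for f in fields):
            raise ValueError(f"{path}: row {i} contains non-binary characters")
        rows.append([int(f) for f in fields])
    if len(np.unique(positions)) != positions.size:
        raise ValueError(f"{path}: duplicate positions")
    if region_length is None:
        region_length = int(positions.max())
    return FounderPanel(np.array(rows, dtype=np.uint8), positions, region_length)


def write_founders_fasta(panel: FounderPanel, path) -> None:
    with open(path, "w") as fh:
        pos = ",".join(str(p) for p in panel.positions)
        fh.write(f";region_length={panel.region_length};positions={pos}\n")
        for i, row in enumerate(panel.haplotypes):
            fh.write(f">founder_{i}\n")
            fh.write("".join(str(int(a)) for a in row) + "\n")


def read_founders_fasta(path) -> FounderPanel:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(";"):
        raise ValueError(f"{path}: missing ';region_length=...;positions=...' header")
    meta = dict(kv.split("=", 1) for kv in lines[0][1:].split(";") if "=" in kv)
    region_length = int(meta["region_length"])
    positions = np.array([int(x) for x in meta["positions"].split(",")])
    haps = []
    seq = None
    for ln in lines[1:]:
        if ln.startswith(">"):
            if seq is not None:
                haps.append(seq)
            seq = ""
        else:
            seq += ln.strip()
    if seq is not None:
        haps.append(seq)
    mat = []
    for i, s in enumerate(haps):
        if len(s) != positions.size or any(ch not in "01" for ch in s):
            raise ValueError(f"{path}: record {i} malformed")
        mat.append([int(ch) for ch in s])
    return FounderPanel(np.array(mat, dtype=np.uint8), positions, region_length)


# ---------------------------------------------------------------------------
# sync-style pool-seq files
# ---------------------------------------------------------------------------


def _sample_labels(T: int, R: int) -> list[str]:
    return [f"gen{i}_rep{k}" for i in range(T) for k in range(R)]


def write_sync(
    data: TrajectoryData,
    positions: Sequence[int],
    path,
    chrom: str = "chr",
) -> None:
    """Write finite-coverage trajectories as a sync file (derived allele ->
    base T, ancestral/remaining coverage -> base A).  Samples are ordered
    generation-major then replicate.  Infinite-coverage data has no integer
    counts and is refused; use :func:`write_long_tsv` instead."""
    if data.infinite_coverage:
        raise ValueError(
            "sync requires integer read counts; infinite-coverage data has none "
            "(write_long_tsv handles exact frequencies)"
        )
    T, K, R = data.shape
    positions = np.asarray(positions)
    if positions.size != K:
        raise ValueError("one position per site required")
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\t" + "\t".join(_sample_labels(T, R)) + "\n")
        for j in range(K):
            fields = [chrom, str(int(positions[j])), ANCESTRAL_BASE]
            for i in range(T):
                for k in range(R):
                    d = int(data.counts[i, j, k])
                    c = int(data.coverages[i, j, k])
                    sextet = {b: 0 for b in _BASES}
                    sextet[DERIVED_BASE] = d
                    sextet[ANCESTRAL_BASE] = c - d
                    fields.append(":".join(str(sextet[b]) for b in _BASES))
            fh.write("\t".join(fields) + "\n")


def read_sync(
    path,
    T: Optional[int] = None,
    R: Optional[int] = None,
    derived_base: str = DERIVED_BASE,
) -> tuple[TrajectoryData, np.ndarray, str]:
    """Read a sync file into (TrajectoryData, positions, chrom).  The sample
    columns are interpreted generation-major then replicate (as written by
    :func:`write_sync`; a header line, if present, is used to infer T and
    R).  Malformed lines raise with their line number."""
    lines = Path(path).read_text().splitlines()
    header = None
    body = []
    for ln in lines:
        if ln.startswith("#"):
            header = ln
        elif ln.strip():
            body.append(ln)
    if header is not None and (T is None or R is None):
        labels = header.lstrip("#").split("\t")[3:]
        gens = {lab.split("_")[0] for lab in labels}
        reps = {lab.split("_")[1] for lab in labels}
        T, R = len(gens), len(reps)
    if T is None or R is None:
        raise ValueError("T and R must be given when the file has no header")
    base_idx = _BASES.index(derived_base)
    counts, covs, positions = [], [], []
    chrom = "chr"
    last_pos = -1
    for li, ln in enumerate(body, start=1):
        fields = ln.split("\t")
        if len(fields) != 3 + T * R:
            raise ValueError(f"{path}:{li}: expected {3 + T * R} fields, got {len(fields)}")
        chrom = fields[0]
        pos = int(fields[1])
        if pos <= last_pos:
            warnings.warn(f"{path}:{li}: non-monotone position {pos}", stacklevel=2)
        last_pos = pos
        positions.append(pos)
        row_d, row_c = [], []
        for f in fields[3:]:
            sextet = [int(x) for x in f.split(":")]
            if len(sextet) != 6 or any(x < 0 for x in sextet):
                raise ValueError(f"{path}:{li}: malformed count sextet {f!r}")
            row_d.append(sextet[base_idx])
            row_c.append(sum(sextet))
        counts.append(row_d)
        covs.append(row_c)
    K = len(positions)
    d = np.array(counts).reshape(K, T, R).transpose(1, 0, 2)
    c = np.array(covs).reshape(K, T, R).transpose(1, 0, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(c > 0, d / np.maximum(c, 1), np.nan)
    return TrajectoryData(frequencies=f, counts=d, coverages=c), np.array(positions), chrom


# ---------------------------------------------------------------------------
# long-format TSV
# ---------------------------------------------------------------------------


def write_long_tsv(
    data: TrajectoryData,
    positions: Sequence[int],
    generations: Sequence[int],
    path,
) -> None:
    T, K, R = data.shape
    rows = []
    for i, gen in enumerate(generations):
        for k in range(R):
            for j in range(K):
                rows.append(
                    {
                        "generation": gen,
                        "replicate": k,
                        "position": int(positions[j]),
                        "count": "" if data.infinite_coverage else int(data.counts[i, j, k]),
                        "coverage": "" if data.infinite_coverage else int(data.coverages[i, j, k]),
                        "frequency": data.frequencies[i, j, k],
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_long_tsv(path) -> tuple[TrajectoryData, np.ndarray, np.ndarray]:
    """Read a long-format TSV back into (TrajectoryData, positions,
    generations)."""
    df = pd.read_csv(path, sep="\t")
    gens = np.sort(df["generation"].unique())
    reps = np.sort(df["replicate"].unique())
    positions = np.sort(df["position"].unique())
    T, K, R = len(gens), len(positions), len(reps)
    gi = {g: i for i, g in enumerate(gens)}
    pj = {p: j for j, p in enumerate(positions)}
    rk = {r: k for k, r in enumerate(reps)}
    freq = np.full((T, K, R), np.nan)
    finite = not df["count"].isna().all()
    d = np.zeros((T, K, R), dtype=np.int64) if finite else None
    c = np.zeros((T, K, R), dtype=np.int64) if finite else None
    for row in df.itertuples(index=False):
        i, j, k = gi[row.generation], pj[row.position], rk[row.replicate]
        freq[i, j, k] = row.frequency
        if finite:
            d[i, j, k] = int(row.count)
            c[i, j, k] = int(row.coverage)
    return TrajectoryData(frequencies=freq, counts=d, coverages=c), positions, gens


def write_results(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
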