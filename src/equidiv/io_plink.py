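"""PLINK-family genotype I/O and genomic-interval export.

Genotypes live in a :class:`GenotypeMatrix`: a samples x markers matrix of
allele-b dosage codes (0 = hom allele-a, 1 = het, 2 = hom allele-b,
``MISSING`` = no call) plus a marker map and a sample registry.  Internal
coordinates are 1-based inclusive base pairs; BED export converts to the
0-based half-open convention.

Both the PLINK text dialect (``.ped``/``.map``) and the binary dialect
(``.bed``/``.bim``/``.fam``, SNP-major v1 layout) are supported losslessly
for calls, marker ids and positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: missing-genotype code used throughout the package
MISSING: int = -1

#: horse autosomes (EquCab-style labelling); all downstream analyses are
#: restricted to this set
HORSE_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 32))

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 1 two-bit codes (per pair of bits, little-endian within the byte):
# 00 hom A1/A1, 01 missing, 10 het, 11 hom A2/A2.  We store allele-b (=A2)
# dosage, so 0<->0b00, 1<->0b10, 2<->0b11, MISSING<->0b01.
_CODE_TO_BITS = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}
_BITS_TO_CODE = np.array([0, MISSING, 1, 2], dtype=np.int8)


class PlinkFormatError(ValueError):
    """Raised when PLINK files are malformed or mutually inconsistent."""


def _ext(prefix: Path, suffix: str) -> Path:
    # Path.with_suffix would clobber dots inside the prefix stem
    return prefix.parent / (prefix.name + suffix)


@dataclass
class GenotypeMatrix:
    """Samples x markers genotype calls with marker map and sample registry.

    Attributes
    ----------
    samples : pandas.DataFrame
        One row per sample, in file order.  Columns ``sample_id`` and
        ``family_id`` always present; ``population`` and ``birth_year`` are
        optional metadata.
    markers : pandas.DataFrame
        One row per marker, sorted by (chromosome, position).  Columns
        ``chrom`` (string label), ``snp_id``, ``pos_bp`` (1-based),
        ``allele_a``, ``allele_b``.
    calls : numpy.ndarray
        ``int8`` array of shape (n_samples, n_markers) with values in
        {0, 1, 2, MISSING}.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray
    autosomes: tuple[str, ...] = HORSE_AUTOSOMES

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of allele-b among non-missing calls.

        Monomorphic or fully missing markers yield 0.
        """
        obs = self.calls != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        dose = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, dose / np.maximum(n_alleles, 1), 0.0)
        return p

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return replace(
            self,
            samples=self.samples.iloc[idx].reset_index(drop=True),
            calls=self.calls[idx, :],
        )

    def take_markers(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return replace(
            self,
            markers=self.markers.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())


@dataclass
class IntervalRecord:
    """A genomic interval in the internal 1-based inclusive convention."""

    chrom: str
    start_bp: int
    end_bp: int
    name: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError(f"interval start {self.start_bp} >= end {self.end_bp}")


def _normalise_markers(
    markers: pd.DataFrame, autosomes: Sequence[str], drop_nonautosomal: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sort by (chromosome, position), restrict to autosomes, dedupe positions.

    Returns the cleaned marker table and the integer index (into the input
    rows) that realises it, so callers can reorder call columns identically.
    Duplicate (chrom, pos) pairs keep the first occurrence; non-autosomal
    labels are dropped — both with a logged count.
    """
    order = {c: i for i, c in enumerate(autosomes)}
    m = markers.reset_index(drop=True).copy()
    m["_orig"] = np.arange(len(m))
    on_auto = m["chrom"].isin(order)
    if drop_nonautosomal and (~on_auto).any():
        log.info("dropping %d non-autosomal markers", int((~on_auto).sum()))
        m = m[on_auto]
    elif not on_auto.all():
        raise PlinkFormatError(
            f"unknown chromosome labels: {sorted(set(m.loc[~on_auto, 'chrom']))[:5]}"
        )
    m = m.assign(_c=m["chrom"].map(order)).sort_values(
        ["_c", "pos_bp", "_orig"], kind="stable"
    )
    dup = m.duplicated(subset=["chrom", "pos_bp"], keep="first")
    if dup.any():
        log.warning("dropping %d duplicate (chrom, pos) markers", int(dup.sum()))
        m = m[~dup]
    idx = m["_orig"].to_numpy()
    m = m.drop(columns=["_c", "_orig"]).reset_index(drop=True)
    return m, idx


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    m = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": str, "snp_id": str},
    )
    m["pos_bp"] = m["pos_bp"].astype(np.int64)
    m["allele_a"] = "A"
    m["allele_b"] = "B"
    return m[["chrom", "snp_id", "pos_bp", "allele_a", "allele_b"]]


def _read_text(prefix: Path, autosomes: Sequence[str]) -> GenotypeMatrix:
    markers = _read_map(_ext(prefix, ".map"))
    fam_rows: list[tuple[str, str]] = []
    geno_rows: list[np.ndarray] = []
    n_m = len(markers)
    allele_a = markers["allele_a"].to_numpy()
    allele_b = markers["allele_b"].to_numpy()
    with open(_ext(prefix, ".ped")) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_m:
                raise PlinkFormatError(
                    f"{prefix}.ped line {line_no}: expected {6 + 2 * n_m} fields, "
                    f"got {len(parts)}"
                )
            fam_rows.append((parts[0], parts[1]))
            a1 = np.array(parts[6::2])
            a2 = np.array(parts[7::2])
            miss = (a1 == "0") | (a2 == "0")
            code = (a1 == allele_b).astype(np.int8) + (a2 == allele_b).astype(np.int8)
            unknown = ~miss & ~(
                ((a1 == allele_a) | (a1 == allele_b))
                & ((a2 == allele_a) | (a2 == allele_b))
            )
            if unknown.any():
                raise PlinkFormatError(
                    f"{prefix}.ped line {line_no}: allele labels do not match the map"
                )
            code[miss] = MISSING
            geno_rows.append(code)
    samples = pd.DataFrame(fam_rows, columns=["family_id", "sample_id"])[
        ["sample_id", "family_id"]
    ]
    calls = (
        np.vstack(geno_rows) if geno_rows else np.empty((0, n_m), dtype=np.int8)
    )
    markers, idx = _normalise_markers(markers, autosomes)
    return GenotypeMatrix(samples, markers, calls[:, idx], tuple(autosomes))


def _write_text(g: GenotypeMatrix, prefix: Path) -> None:
    m = g.markers
    with open(_ext(prefix, ".map"), "w") as fh:
        for row in m.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\n")
    aa = m["allele_a"].to_numpy()
    bb = m["allele_b"].to_numpy()
    # per-marker lookup: code -> "x y" allele pair
    pair = np.empty((4, len(m)), dtype=object)
    pair[0] = np.char.add(np.char.add(aa.astype(str), " "), aa.astype(str))
    pair[1] = np.char.add(np.char.add(aa.astype(str), " "), bb.astype(str))
    pair[2] = np.char.add(np.char.add(bb.astype(str), " "), bb.astype(str))
    pair[3] = "0 0"
    with open(_ext(prefix, ".ped"), "w") as fh:
        for i, srow in enumerate(g.samples.itertuples(index=False)):
            codes = g.calls[i].copy()
            codes[codes == MISSING] = 3
            geno = " ".join(pair[codes, np.arange(len(m))]) if len(m) else ""
            lead = f"{srow.family_id} {srow.sample_id} 0 0 0 -9"
            fh.write(lead + (" " + geno if geno else "") + "\n")


# ---------------------------------------------------------------------------
# binary dialect
# ---------------------------------------------------------------------------

def _read_bim(path: Path) -> pd.DataFrame:
    m = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "allele_a", "allele_b"],
        dtype={"chrom": str, "snp_id": str, "allele_a": str, "allele_b": str},
    )
    m["pos_bp"] = m["pos_bp"].astype(np.int64)
    return m[["chrom", "snp_id", "pos_bp", "allele_a", "allele_b"]]


def _read_binary(prefix: Path, autosomes: Sequence[str]) -> GenotypeMatrix:
    markers = _read_bim(_ext(prefix, ".bim"))
    fam = pd.read_csv(
        _ext(prefix, ".fam"),
        sep=r"\s+",
        header=None,
        names=["family_id", "sample_id", "pat", "mat", "sex", "pheno"],
        dtype={"family_id": str, "sample_id": str},
    )
    samples = fam[["sample_id", "family_id"]].copy()
    n_s, n_m = len(samples), len(markers)
    raw = Path(_ext(prefix, ".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic (not SNP-major PLINK 1)")
    bytes_per_snp = (n_s + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * n_m:
        raise PlinkFormatError(
            f"{prefix}.bed: payload {payload.size} B, expected "
            f"{bytes_per_snp * n_m} B for {n_s} samples x {n_m} markers"
        )
    blocks = payload.reshape(n_m, bytes_per_snp)
    # unpack the four 2-bit fields of every byte, little-endian pair order
    two_bit = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(n_m, bytes_per_snp * 4)[:, :n_s]
    calls = _BITS_TO_CODE[two_bit].T  # (n_samples, n_markers)
    markers, idx = _normalise_markers(markers, autosomes)
    return GenotypeMatrix(samples, markers, calls[:, idx], tuple(autosomes))


def _write_binary(g: GenotypeMatrix, prefix: Path) -> None:
    m = g.markers
    with open(_ext(prefix, ".bim"), "w") as fh:
        for row in m.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\t"
                f"{row.allele_a}\t{row.allele_b}\n"
            )
    with open(_ext(prefix, ".fam"), "w") as fh:
        for srow in g.samples.itertuples(index=False):
            fh.write(f"{srow.family_id} {srow.sample_id} 0 0 0 -9\n")
    n_s, n_m = g.n_samples, g.n_markers
    bits = np.empty((n_m, n_s), dtype=np.uint8)
    ct = g.calls.T
    for code, b in _CODE_TO_BITS.items():
        bits[ct == code] = b
    bytes_per_snp = (n_s + 3) // 4
    padded = np.zeros((n_m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_s] = bits
    quads = padded.reshape(n_m, bytes_per_snp, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_plink(
    prefix: str | Path,
    dialect: str | None = None,
    autosomes: Sequence[str] = HORSE_AUTOSOMES,
    metadata: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a PLINK fileset into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    prefix
        Path prefix; ``prefix.ped``/``.map`` (text) or ``prefix.bed``/
        ``.bim``/``.fam`` (binary) must exist.
    dialect
        "text", "binary", or None to auto-detect (binary preferred).
    autosomes
        Ordered chromosome labels retained for analysis; anything else is
        dropped at load with a logged count.
    metadata
        Optional TSV with a ``sample_id`` column plus e.g. ``population`` /
        ``birth_year``, merged into the sample registry.
    """
    prefix = Path(prefix)
    if dialect is None:
        dialect = "binary" if _ext(prefix, ".bed").exists() else "text"
    if dialect == "binary":
        g = _read_binary(prefix, autosomes)
    elif dialect == "text":
        g = _read_text(prefix, autosomes)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype={"sample_id": str})
        g.samples = g.samples.merge(meta, on="sample_id", how="left")
    return g


def write_plink(g: GenotypeMatrix, prefix: str | Path, dialect: str = "binary") -> None:
    """Write ``g`` as a PLINK fileset readable by :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "binary":
        _write_binary(g, prefix)
    elif dialect == "text":
        _write_text(g, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def intersect_markers(
    a: GenotypeMatrix, b: GenotypeMatrix, key: str = "position"
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two matrices to their shared marker set, in matched order.

    ``key`` selects the join key: marker ids ("id") or (chrom, pos) pairs
    ("position").  Raises if the intersection is empty.
    """
    if key == "id":
        ka = a.markers["snp_id"]
        kb = b.markers["snp_id"]
    elif key == "position":
        ka = a.markers["chrom"].str.cat(a.markers["pos_bp"].astype(str), sep=":")
        kb = b.markers["chrom"].str.cat(b.markers["pos_bp"].astype(str), sep=":")
    else:
        raise ValueError(f"unknown key {key!r}")
    shared = pd.Index(ka).intersection(pd.Index(kb))
    if len(shared) == 0:
        raise ValueError("no shared markers between the two datasets")
    ia = np.flatnonzero(ka.isin(shared).to_numpy())
    ib_lookup = pd.Series(np.arange(len(kb)), index=kb)
    ib = ib_lookup.loc[ka.iloc[ia]].to_numpy()
    log.info(
        "marker intersection: %d of %d / %d markers shared",
        len(shared), len(ka), len(kb),
    )
    return a.take_markers(ia), b.take_markers(ib)


def export_bed(records: Iterable[IntervalRecord], path: str | Path) -> None:
    """Write intervals as browser-extensible-data (BED) lines.

    The internal 1-based inclusive interval [s, e] becomes the 0-based
    half-open (s-1, e).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for r in records:
            cols = [r.chrom, str(r.start_bp - 1), str(r.end_bp), r.name]
            if r.score is not None:
                cols.append(f"{r.score:g}")
            fh.write("\t".join(cols) + "\n")


def import_bed(path: str | Path) -> list[IntervalRecord]:
    """Read a BED file back into internal 1-based inclusive intervals."""
    out: list[IntervalRecord] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else None
            out.append(IntervalRecord(chrom, start + 1, end, name, score))
    return out
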