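"""Data model and on-disk formats: phased VCF, recombination maps, section files.

The pipeline's universal sample representation is the :class:`HaplotypeMatrix`,
a binary haplotypes-by-variants matrix.  A phased diploid VCF with N donors
yields 2N haplotype rows: for each donor the left allele of ``a|b`` becomes row
``<sample>_A`` and the right allele row ``<sample>_B``, interleaved per donor.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pysam

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import SegmentationPlan

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeMatrix",
    "RecombMap",
    "HotspotSet",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_recomb_map",
    "save_segments",
    "load_segments",
]


@dataclass
class HaplotypeMatrix:
    """Binary haplotypes x variants with genomic coordinates.

    ``data`` holds {0,1} allele indicators, one row per haplotype, one column
    per variant; ``positions`` are 1-based bp coordinates, strictly increasing.
    """

    chrom: str
    positions: np.ndarray
    variant_ids: list[str]
    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (haplotypes x variants)")
        n, m = self.data.shape
        if len(self.positions) != m or len(self.variant_ids) != m:
            raise ValueError("positions / variant_ids length must equal the number of variant columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal the number of haplotype rows")
        if m > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("data entries must be 0 or 1")

    @property
    def n_haplotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_variants(self) -> int:
        return self.data.shape[1]

    def subset_variants(self, start: int, end: int) -> "HaplotypeMatrix":
        """Column slice [start, end) as a new matrix."""
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[start:end].copy(),
            variant_ids=list(self.variant_ids[start:end]),
            sample_ids=list(self.sample_ids),
            data=self.data[:, start:end].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.positions, other.positions)
            and list(self.variant_ids) == list(other.variant_ids)
            and list(self.sample_ids) == list(other.sample_ids)
            and np.array_equal(self.data, other.data)
        )


@dataclass
class RecombMap:
    """Ordered recombination-rate intervals for one chromosome.

    Intervals are stored 1-based with inclusive start and exclusive end;
    rates are in cM/Mb.
    """

    chrom: str
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    rates: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.rates)):
            raise ValueError("starts/ends/rates must have equal length")
        if np.any(self.starts >= self.ends):
            raise ValueError("every interval must satisfy start < end")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")
        order = np.argsort(self.starts, kind="stable")
        self.starts = self.starts[order]
        self.ends = self.ends[order]
        self.rates = self.rates[order]

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class HotspotSet:
    """Single-base recombination hotspot loci with intensities, sorted by position."""

    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    intensities: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("hotspot positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


def read_phased_vcf(path: str | Path, min_haplotype_count: int = 0) -> HaplotypeMatrix:
    """Read a phased diploid VCF into a HaplotypeMatrix.

    Each donor contributes two rows (left and right allele of ``a|b``).
    Variants carried by fewer than ``min_haplotype_count`` haplotypes are
    dropped; multiallelic records are skipped with a warning.  Unphased or
    missing genotypes raise ``ValueError`` naming the offending record.
    """
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pysam warns about missing index on plain VCFs
        vf = pysam.VariantFile(path)
    donors = list(vf.header.samples)
    header_contigs = list(vf.header.contigs)
    sample_ids = [f"{d}_{suffix}" for d in donors for suffix in ("A", "B")]
    chrom: str | None = None
    positions: list[int] = []
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        if chrom is None:
            chrom = rec.chrom
        elif rec.chrom != chrom:
            raise ValueError(f"multiple chromosomes in VCF ({chrom!r} and {rec.chrom!r}); supply one at a time")
        col = np.empty(2 * len(donors), dtype=np.uint8)
        for i, donor in enumerate(donors):
            call = rec.samples[donor]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                raise ValueError(f"missing GT for sample {donor} at {rec.chrom}:{rec.pos}")
            if not call.phased:
                raise ValueError(f"unphased GT for sample {donor} at {rec.chrom}:{rec.pos}")
            col[2 * i] = 1 if gt[0] else 0
            col[2 * i + 1] = 1 if gt[1] else 0
        positions.append(rec.pos)
        variant_ids.append(rec.id if rec.id else f"{rec.chrom}_{rec.pos}")
        columns.append(col)
    vf.close()
    if n_skipped:
        logger.warning("skipped %d multiallelic/symbolic records", n_skipped)
    if chrom is None:
        chrom = header_contigs[0] if header_contigs else ""
    n = 2 * len(donors)
    if columns:
        data = np.stack(columns, axis=1)
        order = np.argsort(np.asarray(positions), kind="stable")
        data = data[:, order]
        positions = [positions[i] for i in order]
        variant_ids = [variant_ids[i] for i in order]
        keep = data.sum(axis=0) >= min_haplotype_count
        data = data[:, keep]
        positions = [p for p, k in zip(positions, keep) if k]
        variant_ids = [v for v, k in zip(variant_ids, keep) if k]
    else:
        data = np.zeros((n, 0), dtype=np.uint8)
    return HaplotypeMatrix(chrom=chrom, positions=np.asarray(positions, dtype=np.int64),
                           variant_ids=variant_ids, sample_ids=sample_ids, data=data)


def _donor_names(sample_ids: Sequence[str]) -> list[str]:
    donors = []
    for i in range(0, len(sample_ids), 2):
        a, b = sample_ids[i], sample_ids[i + 1]
        if a.endswith("_A") and b.endswith("_B") and a[:-2] == b[:-2]:
            donors.append(a[:-2])
        else:
            donors.append(f"D{i // 2}")
    return donors


def write_phased_vcf(hm: HaplotypeMatrix, path: str | Path) -> None:
    """Write a HaplotypeMatrix as a phased VCF (consecutive row pairs = donors).

    Alleles are written as placeholder REF=A / ALT=T; the matrix records
    presence/absence only, and the reader reproduces it bit-exactly.
    """
    if hm.n_haplotypes % 2 != 0:
        raise ValueError("haplotype count must be even (two rows per donor)")
    header = pysam.VariantHeader()
    contig = hm.chrom if hm.chrom else "chr1"
    length = int(hm.positions[-1]) + 1000 if hm.n_variants else 1000
    header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    donors = _donor_names(hm.sample_ids)
    for d in donors:
        header.add_sample(d)
    out = pysam.VariantFile(str(path), "w", header=header)
    for j in range(hm.n_variants):
        rec = out.new_record(contig=contig, start=int(hm.positions[j]) - 1,
                             alleles=("A", "T"), id=hm.variant_ids[j])
        for i, donor in enumerate(donors):
            rec.samples[donor]["GT"] = (int(hm.data[2 * i, j]), int(hm.data[2 * i + 1, j]))
            rec.samples[donor].phased = True
        out.write(rec)
    out.close()


def read_recomb_map(path: str | Path, chrom: str, coords: str = "bed") -> RecombMap:
    """Read a tab-separated recombination map, keeping rows of one chromosome.

    Expected columns: chrom, start, end, rate (cM/Mb); one optional header row.
    ``coords="bed"`` treats intervals as 0-based half-open (the common dialect
    for such maps) and shifts starts to the internal 1-based convention;
    ``coords="one-based"`` takes them as already 1-based inclusive-start,
    exclusive-end.
    """
    if coords not in ("bed", "one-based"):
        raise ValueError("coords must be 'bed' or 'one-based'")
    starts: list[int] = []
    ends: list[int] = []
    rates: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"line {lineno}: expected 4 tab-separated columns")
            try:
                start = int(cols[1])
                end = int(cols[2])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"line {lineno}: unparseable interval bounds") from None
            try:
                rate = float(cols[3])
            except ValueError:
                raise ValueError(f"line {lineno}: unparseable recombination rate {cols[3]!r}") from None
            if cols[0] != chrom:
                continue
            if coords == "bed":
                start += 1
                end += 1
            starts.append(start)
            ends.append(end)
            rates.append(rate)
    return RecombMap(chrom=chrom, starts=np.asarray(starts, dtype=np.int64),
                     ends=np.asarray(ends, dtype=np.int64), rates=np.asarray(rates, dtype=float))


# ---------------------------------------------------------------------------
# Section files: one gzipped text file per section plus a JSON manifest.

def _section_filename(index: int) -> str:
    return f"section_{index:04d}.txt.gz"


def save_segments(plan: "SegmentationPlan", hm: HaplotypeMatrix, directory: str | Path) -> Path:
    """Write one file per section of ``plan`` plus a manifest; returns the directory."""
    plan.validate(hm.n_variants)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "chrom": hm.chrom,
        "n_haplotypes": hm.n_haplotypes,
        "n_variants": hm.n_variants,
        "n_artificial": plan.n_artificial,
        "n_ignored_hotspots": plan.n_ignored_hotspots,
        "sections": [],
    }
    for idx, sec in enumerate(plan.sections):
        sub = hm.subset_variants(sec.start, sec.end)
        fname = _section_filename(idx)
        with gzip.open(directory / fname, "wt") as fh:
            fh.write(f"#chrom\t{sub.chrom}\n")
            fh.write("#positions\t" + "\t".join(str(p) for p in sub.positions) + "\n")
            fh.write("#variant_ids\t" + "\t".join(sub.variant_ids) + "\n")
            fh.write("#sample_ids\t" + "\t".join(sub.sample_ids) + "\n")
            for row in sub.data:
                fh.write("".join("1" if v else "0" for v in row) + "\n")
        manifest["sections"].append({
            "file": fname,
            "start": sec.start,
            "end": sec.end,
            "kind": sec.kind,
            "boundary_position": sec.boundary_position,
        })
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_segments(directory: str | Path) -> tuple[list[HaplotypeMatrix], dict]:
    """Load section submatrices saved by :func:`save_segments` (bit-exact)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    sections: list[HaplotypeMatrix] = []
    for entry in manifest["sections"]:
        with gzip.open(directory / entry["file"], "rt") as fh:
            chrom = fh.readline().rstrip("\n").split("\t")[1]
            positions = [int(x) for x in fh.readline().rstrip("\n").split("\t")[1:]]
            variant_ids = fh.readline().rstrip("\n").split("\t")[1:]
            sample_ids = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [np.frombuffer(line.strip().encode(), dtype=np.uint8) - ord("0")
                    for line in fh if line.strip()]
        data = np.stack(rows) if rows else np.zeros((len(sample_ids), 0), dtype=np.uint8)
        sections.append(HaplotypeMatrix(chrom=chrom, positions=np.asarray(positions, dtype=np.int64),
                                        variant_ids=variant_ids, sample_ids=sample_ids,
                                        data=data.astype(np.uint8)))
    return sections, manifest
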