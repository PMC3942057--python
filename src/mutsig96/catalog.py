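"""Somatic SNV parsing and 96-context mutation catalog construction.

Coordinates follow the source-format conventions throughout: mutation
records are 1-based (MAF/VCF), interval tracks are 0-based half-open (BED).
CpG-island membership is tested at the mutated base only.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, ValidationError
from .scheme import (
    COMPLEMENT,
    DEFAULT_SCHEME,
    CategoryScheme,
    collapse_to_pyrimidine,
    parse_label,
)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant."""

    sample_id: str
    contig: str
    position: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValidationError(
                f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.contig}:{self.position}")
        if self.position < 1:
            raise ValidationError(f"position must be 1-based positive, got {self.position}")

    def strand_flipped(self) -> "MutationRecord":
        """The same mutation reported on the opposite strand."""
        return MutationRecord(
            sample_id=self.sample_id,
            contig=self.contig,
            position=self.position,
            ref=COMPLEMENT[self.ref],
            alt=COMPLEMENT[self.alt],
        )


class IntervalSet:
    """Per-contig sorted, merged, 0-based half-open intervals."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._by_contig: dict[str, tuple[list[int], list[int]]] = {}
        if intervals:
            for contig, ivs in intervals.items():
                self._set_contig(contig, ivs)

    def _set_contig(self, contig: str, ivs: Iterable[tuple[int, int]]) -> None:
        merged: list[list[int]] = []
        for start, end in sorted(ivs):
            if start >= end:
                raise ValidationError(f"empty interval [{start}, {end}) on {contig}")
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        self._by_contig[contig] = ([s for s, _ in merged], [e for _, e in merged])

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        raw: dict[str, list[tuple[int, int]]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: BED line needs >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            raw.setdefault(fields[0], []).append((start, end))
        return cls(raw)

    def contains(self, contig: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        entry = self._by_contig.get(contig)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < ends[i]

    def intervals(self, contig: str) -> list[tuple[int, int]]:
        entry = self._by_contig.get(contig, ([], []))
        return list(zip(entry[0], entry[1]))

    @property
    def contigs(self) -> list[str]:
        return sorted(self._by_contig)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig in self.contigs:
                for start, end in self.intervals(contig):
                    fh.write(f"{contig}\t{start}\t{end}\n")


@dataclass
class MutationCatalog:
    """96 x N integer count matrix over a fixed category scheme."""

    counts: np.ndarray
    sample_ids: list[str]
    scheme: CategoryScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96, len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match 96 x {len(self.sample_ids)}"
            )
        if np.any(self.counts < 0):
            raise ValidationError("catalog counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValidationError("catalog counts must be integers")
            self.counts = rounded.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.scheme.labels), columns=self.sample_ids)

    def write_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        df = self.to_frame()
        df.index.name = "category"
        df.to_csv(path, sep="\t")
        if sidecar:
            side = Path(path).with_suffix(Path(path).suffix + ".provenance.json")
            side.write_text(json.dumps(self.provenance, indent=2, default=str) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        scheme = DEFAULT_SCHEME
        if list(df.index) != list(scheme.labels):
            raise ValidationError(f"{path}: row labels do not match the 96-category scheme")
        return cls(
            counts=df.to_numpy(),
            sample_ids=[str(c) for c in df.columns],
            scheme=scheme,
            provenance={"source": str(path)},
        )


# ---------------------------------------------------------------------------
# parsing


def _parse_maf_lite(path: str | Path) -> tuple[list[MutationRecord], dict]:
    records: list[MutationRecord] = []
    skipped = 0
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise ValidationError(f"{path}:{lineno}: MAF-lite rows need >=5 columns")
        if lineno == 1 and not fields[2].lstrip("-").isdigit():
            continue  # header row
        sample, contig, pos_s, ref, alt = fields[:5]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: non-integer position {pos_s!r}") from exc
        ref, alt = ref.upper(), alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _VALID_BASES or alt not in _VALID_BASES or ref == alt:
            skipped += 1
            continue
        try:
            records.append(MutationRecord(sample, contig, pos, ref, alt))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return records, {"skipped_non_snv": skipped}


def _parse_vcf(path: str | Path) -> tuple[list[MutationRecord], dict]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    default_sample = Path(path).name.removesuffix(".gz").removesuffix(".vcf")
    records: list[MutationRecord] = []
    skipped = 0
    for variant in vcf:
        alts = variant.ALT
        if len(variant.REF) != 1 or len(alts) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        ref, alt = variant.REF.upper(), alts[0].upper()
        if ref not in _VALID_BASES or alt not in _VALID_BASES or ref == alt:
            skipped += 1
            continue
        if samples:
            # 0 HOM_REF / 1 HET / 2 UNKNOWN / 3 HOM_ALT
            for sample, gt in zip(samples, variant.gt_types):
                if gt in (1, 3):
                    records.append(MutationRecord(sample, variant.CHROM, variant.POS, ref, alt))
        else:
            records.append(MutationRecord(default_sample, variant.CHROM, variant.POS, ref, alt))
    return records, {"skipped_non_snv": skipped}


def parse_mutations(path: str | Path, format: str = "maf-lite") -> list[MutationRecord]:
    """Read biallelic somatic SNVs from a MAF-lite TSV or a VCF.

    Non-SNV rows (indels, multiallelic sites) are skipped, not fatal; the
    skip count is available through :func:`parse_mutations_with_stats`.
    """
    return parse_mutations_with_stats(path, format)[0]


def parse_mutations_with_stats(
    path: str | Path, format: str = "maf-lite"
) -> tuple[list[MutationRecord], dict]:
    if not Path(path).exists():
        raise ValidationError(f"no such file: {path}")
    if format == "maf-lite":
        return _parse_maf_lite(path)
    if format == "vcf":
        return _parse_vcf(path)
    raise ValidationError(f"unknown mutation format {format!r}")


# ---------------------------------------------------------------------------
# context extraction


def _fetch_triplet(genome, contig: str, position: int) -> str:
    """Reference bases at [position-1, position+1], 1-based inclusive."""
    try:
        seq = genome[contig]
    except KeyError as exc:
        raise DataIntegrityError(f"contig {contig!r} absent from reference") from exc
    if isinstance(seq, str):
        if position < 2 or position + 1 > len(seq):
            raise DataIntegrityError(f"{contig}:{position} too close to contig edge")
        return seq[position - 2 : position + 1].upper()
    # pyfaidx FastaRecord (or anything sliceable with 0-based coordinates)
    if position < 2 or position + 1 > len(seq):
        raise DataIntegrityError(f"{contig}:{position} too close to contig edge")
    return str(seq[position - 2 : position + 1]).upper()


def pyrimidine_context(genome, record: MutationRecord) -> str:
    """Category label for a record given its reference genome.

    ``genome`` may be a ``dict`` of contig -> sequence or a ``pyfaidx.Fasta``.
    Raises :class:`DataIntegrityError` on ref mismatch or contig-edge
    positions and :class:`ValidationError` on ambiguous (non-ACGT) context.
    """
    triplet = _fetch_triplet(genome, record.contig, record.position)
    five, ref_base, three = triplet[0], triplet[1], triplet[2]
    if any(b not in _VALID_BASES for b in triplet):
        raise ValidationError(f"ambiguous base in context {triplet} at {record.contig}:{record.position}")
    if ref_base != record.ref:
        raise DataIntegrityError(
            f"ref mismatch at {record.contig}:{record.position}: record {record.ref}, genome {ref_base}"
        )
    sub, five_c, three_c = collapse_to_pyrimidine(record.ref, record.alt, five, three)
    return DEFAULT_SCHEME.label_for(sub, five_c, three_c)


def build_catalog(
    records: Sequence[MutationRecord],
    genome,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> MutationCatalog:
    """Assemble a 96 x N catalog, one column per sample in first-appearance order.

    Duplicate records (identical sample/contig/position/ref/alt) are counted
    once; unmappable records (ref mismatch, ambiguous context, contig edge)
    are excluded. All tallies land in ``provenance``.
    """
    sample_order: list[str] = []
    sample_index: dict[str, int] = {}
    seen: set[tuple] = set()
    n_dup = n_ref_mismatch = n_ambiguous = 0
    assignments: list[tuple[int, int]] = []

    for rec in records:
        key = (rec.sample_id, rec.contig, rec.position, rec.ref, rec.alt)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        if rec.sample_id not in sample_index:
            sample_index[rec.sample_id] = len(sample_order)
            sample_order.append(rec.sample_id)
        try:
            label = pyrimidine_context(genome, rec)
        except DataIntegrityError:
            n_ref_mismatch += 1
            continue
        except ValidationError:
            n_ambiguous += 1
            continue
        assignments.append((scheme.index(label), sample_index[rec.sample_id]))

    if not assignments:
        raise ValidationError("no valid records: cannot build an empty catalog")

    counts = np.zeros((96, len(sample_order)), dtype=np.int64)
    for row, col in assignments:
        counts[row, col] += 1
    return MutationCatalog(
        counts=counts,
        sample_ids=sample_order,
        scheme=scheme,
        provenance={
            "n_input_records": len(records),
            "n_retained": len(assignments),
            "n_duplicates": n_dup,
            "n_ref_mismatch_or_edge": n_ref_mismatch,
            "n_ambiguous_context": n_ambiguous,
        },
    )


def xcg_predicate(label: str) -> bool:
    """Default stratification pattern: C>T with a 3' G, any 5' base."""
    sub, _, three = parse_label(label)
    return sub == "C>T" and three == "G"


def stratify_by_intervals(
    records: Sequence[MutationRecord],
    genome,
    intervals: IntervalSet,
    pattern: Callable[[str], bool] = xcg_predicate,
) -> tuple[list[MutationRecord], list[MutationRecord], list[MutationRecord]]:
    """Split pattern-matching records by interval membership of the mutated base.

    Returns (matching-inside, matching-outside, not-matching); the three
    buckets partition the input. Records whose category cannot be computed
    fall into the not-matching bucket.
    """
    inside: list[MutationRecord] = []
    outside: list[MutationRecord] = []
    other: list[MutationRecord] = []
    for rec in records:
        try:
            label = pyrimidine_context(genome, rec)
        except (DataIntegrityError, ValidationError):
            other.append(rec)
            continue
        if not pattern(label):
            other.append(rec)
        elif intervals.contains(rec.contig, rec.position - 1):
            inside.append(rec)
        else:
            outside.append(rec)
    return inside, outside, other


def write_maf_lite(records: Iterable[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\n")
        for rec in records:
            fh.write(f"{rec.sample_id}\t{rec.contig}\t{rec.position}\t{rec.ref}\t{rec.alt}\n")
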