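"""Per-chromosome-arm read counting for LINE-1 amplicon (mFast-SeqS style) libraries.

Aligned single-end reads are filtered on mapping quality (MAPQ >= 15 by
default), assigned to the chromosome arm containing their leftmost aligned
base, and tallied. The short arms of the acrocentric chromosomes 13, 14, 15
and 22 as well as the whole of chromosome Y carry too few informative LINE-1
elements and are excluded from analysis; their reads are discarded before
normalization. Samples whose retained read yield falls below 90,000 reads are
flagged for re-sequencing (QC flag only — no re-sequencing logic here).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

#: Arms excluded from analysis: acrocentric short arms plus all of chrY.
DEFAULT_EXCLUDED_ARMS = frozenset({"13p", "14p", "15p", "22p", "Yp", "Yq"})

#: Retained-read yield below which a sample is flagged for re-sequencing.
MIN_READS_QC = 90_000

_EXPECTED_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y"]


def _norm_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class ArmDefinition:
    """One chromosome arm as a 0-based half-open genomic interval."""

    chromosome: str  # without "chr" prefix, e.g. "1", "X"
    arm: str  # "p" or "q"
    start: int
    end: int
    included: bool = True

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if not self.start < self.end:
            raise ValueError(f"arm {self.name}: start {self.start} >= end {self.end}")

    @property
    def name(self) -> str:
        return f"{self.chromosome}{self.arm}"


@dataclass
class ArmCountVector:
    """One sample's read counts over the included chromosome arms."""

    sample_id: str
    counts: dict[str, int]
    total_reads: int = field(init=False)
    qc_low_yield: bool = field(default=False)
    retained_reads: int | None = None  # retained (post-MAPQ) yield incl. excluded arms

    def __post_init__(self) -> None:
        for arm, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count for arm {arm} is not a non-negative integer: {c}")
        self.counts = {a: int(c) for a, c in self.counts.items()}
        self.total_reads = int(sum(self.counts.values()))
        if self.retained_reads is None:
            self.retained_reads = self.total_reads
        self.qc_low_yield = self.retained_reads < MIN_READS_QC


@dataclass
class CountingStats:
    """Read-fate tally; categories partition the input reads."""

    assigned: int = 0
    unmapped: int = 0
    low_mapq: int = 0
    excluded_arm: int = 0
    unassigned: int = 0  # chromosome absent from the arm definitions
    secondary_supplementary: int = 0

    @property
    def total(self) -> int:
        return (
            self.assigned
            + self.unmapped
            + self.low_mapq
            + self.excluded_arm
            + self.unassigned
            + self.secondary_supplementary
        )


def default_cytoband_path() -> Path:
    """Path to the bundled condensed hg19 cytoband table."""
    return Path(str(resources.files("aneuscore.data") / "hg19_cytoband_condensed.tsv"))


def load_arm_definitions(
    cytoband_source: str | Path | None = None,
    excluded_arms: Iterable[str] = DEFAULT_EXCLUDED_ARMS,
    exclude_21p: bool = False,
) -> list[ArmDefinition]:
    """Build p/q arm intervals from a UCSC cytoBand-style TSV.

    The p arm spans [0, centromere boundary) and the q arm [boundary,
    chromosome end), where the boundary is the transition between p- and
    q-named bands. Requires bands for chr1-22, chrX and chrY.

    Parameters
    ----------
    cytoband_source
        Path to a cytoBand TSV (chrom, start, end, band, stain). Defaults to
        the bundled condensed hg19 table.
    excluded_arms
        Arm names flagged ``included=False`` (reads there are discarded).
    exclude_21p
        Also exclude 21p (acrocentric, but not in the default exclusion set).
    """
    path = Path(cytoband_source) if cytoband_source is not None else default_cytoband_path()
    excluded = set(excluded_arms)
    if exclude_21p:
        excluded.add("21p")

    bands: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            chrom, start, end, band = fields[0], fields[1], fields[2], fields[3]
            chrom = _norm_chrom(chrom)
            if "_" in chrom:  # alternate/random contigs in full UCSC files
                continue
            if not re.match(r"^[pq]", band):
                raise ValueError(
                    f"{path}:{lineno}: unparseable band name {band!r} on chr{chrom}"
                )
            bands.setdefault(chrom, {"p": [], "q": []})[band[0]].append((int(start), int(end)))

    missing = [c for c in _EXPECTED_CHROMS if c not in bands]
    if missing:
        raise ValueError(f"cytoband file {path} lacks chromosome(s): {', '.join(missing)}")

    arms: list[ArmDefinition] = []
    for chrom in _EXPECTED_CHROMS:
        for arm_letter in ("p", "q"):
            intervals = bands[chrom][arm_letter]
            if not intervals:
                raise ValueError(f"chromosome {chrom} has no {arm_letter}-arm bands")
        p_end = max(e for _, e in bands[chrom]["p"])
        q_start = min(s for s, _ in bands[chrom]["q"])
        if p_end != q_start:
            raise ValueError(
                f"chromosome {chrom}: p/q bands not contiguous ({p_end} != {q_start})"
            )
        chrom_end = max(e for _, e in bands[chrom]["q"])
        name_p, name_q = f"{chrom}p", f"{chrom}q"
        arms.append(ArmDefinition(chrom, "p", 0, p_end, name_p not in excluded))
        arms.append(ArmDefinition(chrom, "q", q_start, chrom_end, name_q not in excluded))
    return arms


def included_arm_names(arms: Sequence[ArmDefinition]) -> list[str]:
    return [a.name for a in arms if a.included]


def count_reads_per_arm(
    alignments: str | Path | pysam.AlignmentFile | Iterable,
    arms: Sequence[ArmDefinition],
    mapq_min: int = 15,
    sample_id: str | None = None,
) -> tuple[ArmCountVector, CountingStats]:
    """Count MAPQ-filtered reads per included chromosome arm.

    Each retained primary alignment is assigned to the arm containing its
    leftmost aligned base (0-based). Reads on excluded arms are dropped and do
    not enter ``total_reads``; the low-yield QC flag is set from the retained
    read count *before* arm exclusion. Reads on chromosomes absent from the
    arm definitions go to an ``unassigned`` bucket rather than erroring.
    """
    close_me = None
    if isinstance(alignments, (str, Path)):
        path = Path(alignments)
        if sample_id is None:
            sample_id = path.stem
        mode = "rb" if path.suffix == ".bam" else "r"
        alignments = close_me = pysam.AlignmentFile(str(path), mode)
    if isinstance(alignments, pysam.AlignmentFile):
        reads = alignments.fetch(until_eof=True)
    else:
        reads = iter(alignments)

    by_chrom: dict[str, list[ArmDefinition]] = {}
    for a in arms:
        by_chrom.setdefault(a.chromosome, []).append(a)

    counts = {a.name: 0 for a in arms if a.included}
    stats = CountingStats()
    try:
        for read in reads:
            if read.is_secondary or read.is_supplementary:
                stats.secondary_supplementary += 1
                continue
            if read.is_unmapped:
                stats.unmapped += 1
                continue
            if read.mapping_quality < mapq_min:
                stats.low_mapq += 1
                continue
            chrom = _norm_chrom(read.reference_name)
            pos = read.reference_start  # 0-based leftmost
            arm = next(
                (a for a in by_chrom.get(chrom, ()) if a.start <= pos < a.end), None
            )
            if arm is None:
                stats.unassigned += 1
            elif arm.included:
                counts[arm.name] += 1
                stats.assigned += 1
            else:
                stats.excluded_arm += 1
    finally:
        if close_me is not None:
            close_me.close()

    retained = stats.assigned + stats.excluded_arm + stats.unassigned
    vec = ArmCountVector(
        sample_id=sample_id or "sample", counts=counts, retained_reads=retained
    )
    return vec, stats


def read_count_table(
    path: str | Path, arms: Sequence[ArmDefinition]
) -> list[ArmCountVector]:
    """Load an arm-count TSV (rows = arms, columns = samples) and validate it.

    The row index must equal the included arm set of ``arms``; excluded arms
    (e.g. 13p) in the table are an error unless the exclusion configuration is
    changed upstream. Cells must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    expected = set(included_arm_names(arms))
    got = set(df.index.astype(str))
    unknown = got - {a.name for a in arms}
    if unknown:
        raise ValueError(f"{path}: unknown arm name(s): {sorted(unknown)}")
    excluded_present = got - expected
    if excluded_present:
        raise ValueError(
            f"{path}: arm(s) excluded by configuration present in table: "
            f"{sorted(excluded_present)}"
        )
    missing = expected - got
    if missing:
        raise ValueError(f"{path}: missing included arm(s): {sorted(missing)}")

    vectors = []
    for col in df.columns:
        series = df[col]
        bad = series[(series < 0) | (series != series.astype(int))]
        if len(bad):
            raise ValueError(
                f"{path}: non-integer or negative count at arm {bad.index[0]!r}, "
                f"sample {col!r}: {bad.iloc[0]}"
            )
        vectors.append(ArmCountVector(sample_id=str(col), counts=series.astype(int).to_dict()))
    return vectors


def write_count_table(vectors: Sequence[ArmCountVector], path: str | Path) -> None:
    """Write an arm-count TSV, rows = arms, columns = samples."""
    df = pd.DataFrame({v.sample_id: pd.Series(v.counts) for v in vectors})
    df.index.name = "arm"
    df.to_csv(path, sep="\t")


def counts_frame(vectors: Sequence[ArmCountVector]) -> pd.DataFrame:
    """Arm x sample DataFrame view of a list of count vectors."""
    df = pd.DataFrame({v.sample_id: pd.Series(v.counts) for v in vectors})
    df.index.name = "arm"
    return df
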