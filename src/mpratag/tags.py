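"""Tag extraction, tag-to-construct association, and tag counting.

Reporter transcripts carry a 20-nt random tag between two fixed anchor
sequences (a restriction site plus ``TAG`` on the 5' side, a second
restriction site on the 3' side).  Tags are matched exactly — no error
correction — because 20-nt random tags in a ~50-construct pool are far
apart in sequence space.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO

from mpratag.library import Construct, NEGATIVE_CONTROL_ID

TAG_LEN = 20
ANCHOR_5P = "TCTAGATAG"  # XbaI site + TAG
ANCHOR_3P = "GGCCGGCC"  # FseI site

#: Junction sequence marking the insert-less (negative control) backbone:
#: the two cloning sites directly abutting.  Configurable because it is a
#: property of the vector, not of the assay design.
DEFAULT_NEG_JUNCTION = "GGTACCGCTAGC"  # KpnI + NheI

DNA_ALPHABET = frozenset("ACGT")

ASSAY_NAMES = ("RTplus", "RTminus", "DNA")


class TagProcessingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TagAssignment:
    """One tag's association with a construct (or lack thereof)."""

    tag: str
    status: str  # unique | ambiguous | unassigned
    construct_id: str | None = None
    support: int = 0

    def __post_init__(self) -> None:
        if len(self.tag) != TAG_LEN or not set(self.tag) <= DNA_ALPHABET:
            raise ValueError(f"tag must be {TAG_LEN} nt of A/C/G/T, got {self.tag!r}")
        if self.status not in ("unique", "ambiguous", "unassigned"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "unique") != (self.construct_id is not None):
            raise ValueError("construct_id present iff status is unique")


@dataclass
class SampleCounts:
    """Tag-level counts for one (cell_line, replicate, assay) sample."""

    cell_line: str
    replicate: int
    assay: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_NAMES:
            raise ValueError(f"assay must be one of {ASSAY_NAMES}, got {self.assay!r}")
        for tag, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for tag {tag}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.cell_line, self.replicate, self.assay)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


class CountResult(NamedTuple):
    sample: SampleCounts
    discarded: int  # reads with no tag or a non-whitelist tag


def extract_tag(read: str) -> str | None:
    """Return the 20-nt tag in a read, or None.

    The tag is the 20 nt immediately after the single occurrence of the 5'
    anchor, and must be N-free and immediately followed by the 3' anchor.
    Reads with more than one 5' anchor are treated as chimeric and yield
    None.
    """
    read = read.upper()
    first = read.find(ANCHOR_5P)
    if first == -1:
        return None
    if read.find(ANCHOR_5P, first + 1) != -1:  # multi-anchor: chimera
        return None
    start = first + len(ANCHOR_5P)
    tag = read[start : start + TAG_LEN]
    if len(tag) < TAG_LEN or not set(tag) <= DNA_ALPHABET:
        return None
    if not read.startswith(ANCHOR_3P, start + TAG_LEN):
        return None
    return tag


def read_sequences(path) -> Iterator[str]:
    """Yield read sequences from a FASTA or FASTQ file (quality ignored)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        fmt = "fastq"
    elif suffix in (".fa", ".fasta", ".fna"):
        fmt = "fasta"
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            first = fh.read(1)
        fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield str(rec.seq)


def _match_constructs(
    read: str, constructs: list[Construct], neg_junction: str
) -> list[str]:
    """Construct ids whose insert occurs in the read (negative control by
    its backbone junction)."""
    hits = [
        c.construct_id
        for c in constructs
        if c.insert_sequence and c.insert_sequence in read
    ]
    if not hits:
        for c in constructs:
            if c.kind == "negative_control" and neg_junction in read:
                hits.append(c.construct_id)
                break
    return hits


def associate_tags(
    reads: Iterable[str],
    constructs: list[Construct],
    *,
    min_support: int = 2,
    neg_junction: str = DEFAULT_NEG_JUNCTION,
    require_coverage: bool = True,
) -> list[TagAssignment]:
    """Associate tags with constructs from construct-sequencing reads.

    Each read contributes one (tag, construct) observation when both a tag
    and exactly one construct insert are found in it.  A tag seen with two
    or more constructs is ambiguous; a tag whose reads match no construct
    is unassigned; a tag seen with one construct in >= ``min_support``
    reads is unique.

    With ``require_coverage`` (the default), a construct that ends up with
    zero unique tags raises :class:`TagProcessingError` naming it.
    """
    tag_construct: dict[str, Counter] = defaultdict(Counter)
    tag_reads: Counter = Counter()
    for read in reads:
        read = read.upper()
        tag = extract_tag(read)
        if tag is None:
            continue
        tag_reads[tag] += 1
        hits = _match_constructs(read, constructs, neg_junction)
        if len(hits) == 1:
            tag_construct[tag][hits[0]] += 1
        elif len(hits) > 1:
            # read itself ambiguous: taint the tag
            for h in hits:
                tag_construct[tag][h] += 1

    assignments: list[TagAssignment] = []
    for tag in sorted(tag_reads):
        support = tag_reads[tag]
        owners = tag_construct.get(tag, Counter())
        if len(owners) >= 2:
            assignments.append(TagAssignment(tag=tag, status="ambiguous", support=support))
        elif len(owners) == 1 and support >= min_support:
            (cid,) = owners
            assignments.append(
                TagAssignment(tag=tag, status="unique", construct_id=cid, support=support)
            )
        else:
            assignments.append(TagAssignment(tag=tag, status="unassigned", support=support))

    if require_coverage:
        covered = {a.construct_id for a in assignments if a.status == "unique"}
        missing = [c.construct_id for c in constructs if c.construct_id not in covered]
        if missing:
            raise TagProcessingError(
                "no unique tag recovered for construct(s): " + ", ".join(missing)
            )
    return assignments


def count_tags(
    reads: Iterable[str],
    assignments: list[TagAssignment],
    *,
    cell_line: str,
    replicate: int,
    assay: str,
) -> CountResult:
    """Count whitelist-tag occurrences in one assay sample.

    The whitelist is the set of uniquely assigned tags.  Every read either
    increments exactly one whitelist tag or the discard tally, so
    counted + discarded == number of input reads.
    """
    whitelist = {a.tag for a in assignments if a.status == "unique"}
    counts: dict[str, int] = {tag: 0 for tag in sorted(whitelist)}
    discarded = 0
    for read in reads:
        tag = extract_tag(read)
        if tag is not None and tag in whitelist:
            counts[tag] += 1
        else:
            discarded += 1
    sample = SampleCounts(cell_line=cell_line, replicate=replicate, assay=assay, counts=counts)
    return CountResult(sample=sample, discarded=discarded)


def aggregate_by_construct(
    counts: SampleCounts, assignments: list[TagAssignment]
) -> dict[str, int]:
    """Pool tag counts per construct (unique assignments only).

    Constructs that own tags but saw none in this sample get 0; ambiguous
    and unassigned tags never contribute.
    """
    tag_to_construct = {
        a.tag: a.construct_id for a in assignments if a.status == "unique"
    }
    out: dict[str, int] = {}
    for cid in tag_to_construct.values():
        out.setdefault(cid, 0)
    for tag, n in counts.counts.items():
        cid = tag_to_construct.get(tag)
        if cid is not None:
            out[cid] += n
    return out


# ---------------------------------------------------------------------------
# TSV interfaces

def write_assignments_tsv(assignments: Iterable[TagAssignment], path) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tag", "construct_id", "status", "support"])
        for a in assignments:
            w.writerow([a.tag, a.construct_id or "", a.status, a.support])


def read_assignments_tsv(path) -> list[TagAssignment]:
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                TagAssignment(
                    tag=row["tag"],
                    construct_id=row["construct_id"] or None,
                    status=row["status"],
                    support=int(row["support"]),
                )
            )
    return out


def write_sample_counts_tsv(samples: Iterable[SampleCounts], path) -> None:
    """Tag-level count table: cell_line, replicate, assay, tag, count."""
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["cell_line", "replicate", "assay", "tag", "count"])
        for s in samples:
            for tag in sorted(s.counts):
                w.writerow([s.cell_line, s.replicate, s.assay, tag, s.counts[tag]])


def read_sample_counts_tsv(path) -> list[SampleCounts]:
    by_key: dict[tuple[str, int, str], SampleCounts] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["cell_line"], int(row["replicate"]), row["assay"])
            if key not in by_key:
                by_key[key] = SampleCounts(
                    cell_line=key[0], replicate=key[1], assay=key[2]
                )
            sample = by_key[key]
            if row["tag"] in sample.counts:
                raise TagProcessingError(
                    f"{path}: duplicate tag {row['tag']} for sample {key}"
                )
            sample.counts[row["tag"]] = int(row["count"])
    return list(by_key.values())
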