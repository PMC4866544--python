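"""Variant library: allele pairs, reporter constructs, and their table formats.

A library is a list of :class:`VariantPair` records, each describing one
binding-site locus with an ancestral and a derived allele plus 25 nt of
flanking sequence on each side.  ``build_constructs`` expands the library
into the full set of reporter constructs: two per variant (one per allele)
plus one positive and one negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, TextIO

FLANK_LEN = 25
DNA_ALPHABET = frozenset("ACGT")

VARIANT_TABLE_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "ancestral",
    "derived",
    "flank5",
    "flank3",
    "tf_name",
)

#: Insert used for the positive-control construct.  A stand-in for a strong
#: viral enhancer; any fixed non-library sequence works because the positive
#: control is never analyzed statistically.
POSITIVE_CONTROL_INSERT = (
    "GACATTGATTATTGACTAGTTATTAATAGTAATCAATTACGGGGTCATTAGTTCATAGCC"
)

NEGATIVE_CONTROL_ID = "negative_control"
POSITIVE_CONTROL_ID = "positive_control"


class VariantTableError(ValueError):
    """Raised when a variant table fails validation."""


def _check_dna(s: str, what: str, row: int) -> None:
    if not s or not set(s) <= DNA_ALPHABET:
        raise VariantTableError(
            f"row {row}: {what} contains non-ACGT characters or is empty: {s!r}"
        )


@dataclass(frozen=True)
class VariantPair:
    """One binding-site locus with its ancestral/derived allele pair.

    Coordinates are 1-based; allele strings are reported on the plus strand
    with a shared left anchor for indels (e.g. ``AG`` vs ``A``), no
    normalization applied.
    """

    variant_id: str
    chrom: str
    pos: int
    ancestral_allele: str
    derived_allele: str
    flank5: str
    flank3: str
    tf_name: str = ""

    def __post_init__(self) -> None:
        for name in ("flank5", "flank3"):
            seq = getattr(self, name)
            if len(seq) != FLANK_LEN or not set(seq) <= DNA_ALPHABET:
                raise VariantTableError(
                    f"{self.variant_id}: {name} must be {FLANK_LEN} nt of A/C/G/T, "
                    f"got {seq!r}"
                )
        for name in ("ancestral_allele", "derived_allele"):
            seq = getattr(self, name)
            if not seq or not set(seq) <= DNA_ALPHABET:
                raise VariantTableError(
                    f"{self.variant_id}: {name} must be non-empty A/C/G/T, got {seq!r}"
                )
        if self.ancestral_allele == self.derived_allele:
            raise VariantTableError(
                f"{self.variant_id}: ancestral and derived alleles are identical"
            )

    def insert_sequence(self, allele_state: str) -> str:
        """Construct insert for one allele: flank5 + allele + flank3."""
        if allele_state == "ancestral":
            allele = self.ancestral_allele
        elif allele_state == "derived":
            allele = self.derived_allele
        else:
            raise ValueError(f"allele_state must be ancestral|derived, got {allele_state}")
        return self.flank5 + allele + self.flank3


@dataclass(frozen=True)
class Construct:
    """One reporter construct in the transfected pool."""

    construct_id: str
    kind: str  # variant_allele | positive_control | negative_control
    insert_sequence: str
    variant_id: str | None = None
    allele_state: str | None = None  # ancestral | derived, iff variant_allele

    def __post_init__(self) -> None:
        if self.kind not in ("variant_allele", "positive_control", "negative_control"):
            raise ValueError(f"bad construct kind {self.kind!r}")
        if self.kind == "variant_allele":
            if self.variant_id is None or self.allele_state not in ("ancestral", "derived"):
                raise ValueError(
                    f"{self.construct_id}: variant_allele requires variant_id and allele_state"
                )
        elif self.variant_id is not None or self.allele_state is not None:
            raise ValueError(f"{self.construct_id}: controls carry no variant fields")
        if self.kind == "negative_control" and self.insert_sequence != "":
            raise ValueError("negative control must have an empty insert")


def allele_construct_id(variant_id: str, allele_state: str) -> str:
    return f"{variant_id}|{allele_state}"


def read_variant_table(path) -> list[VariantPair]:
    """Read a variant-library TSV with the 8 canonical columns.

    The whole file is rejected with a row-identifying message on the first
    malformed row (wrong flank length, non-ACGT characters, duplicate
    variant_id, non-integer position).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise VariantTableError(f"{path}: empty variant table")
    header = tuple(lines[0].split("\t"))
    if header != VARIANT_TABLE_COLUMNS:
        raise VariantTableError(
            f"{path}: header must be {list(VARIANT_TABLE_COLUMNS)}, got {list(header)}"
        )
    pairs: list[VariantPair] = []
    seen: set[str] = set()
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(VARIANT_TABLE_COLUMNS):
            raise VariantTableError(
                f"{path} row {i}: expected {len(VARIANT_TABLE_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        rec = dict(zip(VARIANT_TABLE_COLUMNS, fields))
        if rec["variant_id"] in seen:
            raise VariantTableError(
                f"{path} row {i}: duplicate variant_id {rec['variant_id']!r}"
            )
        seen.add(rec["variant_id"])
        try:
            pos = int(rec["pos"])
        except ValueError:
            raise VariantTableError(
                f"{path} row {i}: pos is not an integer: {rec['pos']!r}"
            ) from None
        try:
            pair = VariantPair(
                variant_id=rec["variant_id"],
                chrom=rec["chrom"],
                pos=pos,
                ancestral_allele=rec["ancestral"],
                derived_allele=rec["derived"],
                flank5=rec["flank5"],
                flank3=rec["flank3"],
                tf_name=rec["tf_name"],
            )
        except VariantTableError as exc:
            raise VariantTableError(f"{path} row {i}: {exc}") from None
        pairs.append(pair)
    return pairs


def write_variant_table(pairs: Iterable[VariantPair], path) -> None:
    """Write the TSV that :func:`read_variant_table` reads (round-trip safe)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(VARIANT_TABLE_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                "\t".join(
                    [
                        p.variant_id,
                        p.chrom,
                        str(p.pos),
                        p.ancestral_allele,
                        p.derived_allele,
                        p.flank5,
                        p.flank3,
                        p.tf_name,
                    ]
                )
                + "\n"
            )


def build_constructs(library: list[VariantPair]) -> list[Construct]:
    """Expand a variant library to the full construct set.

    Returns 2N variant constructs plus one positive and one negative
    control.  Warns if two different constructs share an insert sequence,
    which would make association by sequence ambiguous.
    """
    if not library:
        raise ValueError("empty variant library")
    constructs: list[Construct] = []
    for pair in library:
        for state in ("ancestral", "derived"):
            constructs.append(
                Construct(
                    construct_id=allele_construct_id(pair.variant_id, state),
                    kind="variant_allele",
                    insert_sequence=pair.insert_sequence(state),
                    variant_id=pair.variant_id,
                    allele_state=state,
                )
            )
    constructs.append(
        Construct(
            construct_id=POSITIVE_CONTROL_ID,
            kind="positive_control",
            insert_sequence=POSITIVE_CONTROL_INSERT,
        )
    )
    constructs.append(
        Construct(
            construct_id=NEGATIVE_CONTROL_ID,
            kind="negative_control",
            insert_sequence="",
        )
    )
    by_seq: dict[str, str] = {}
    for c in constructs:
        if not c.insert_sequence:
            continue
        if c.insert_sequence in by_seq:
            warnings.warn(
                f"constructs {by_seq[c.insert_sequence]} and {c.construct_id} "
                "share an insert sequence; sequence-based association will be "
                "ambiguous",
                stacklevel=2,
            )
        else:
            by_seq[c.insert_sequence] = c.construct_id
    return constructs


def write_constructs_fasta(constructs: Iterable[Construct], handle_or_path) -> None:
    """FASTA export of construct insert sequences, one record per construct."""

    def _write(fh: TextIO) -> None:
        for c in constructs:
            fh.write(f">{c.construct_id}\n{c.insert_sequence}\n")

    if hasattr(handle_or_path, "write"):
        _write(handle_or_path)
    else:
        with open(handle_or_path, "wt", encoding="utf-8") as fh:
            _write(fh)
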