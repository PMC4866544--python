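"""Synthetic reporter-assay data with known ground truth.

Generates variant libraries, tag maps, RT+/RT-/DNA count tables, and raw
reads that emulate the statistical structure of the tag-counting
experiment: per-replicate molar-ratio imbalance of the plasmid pool,
DNA carryover into the RNA channels, extra-multinomial (gamma) noise on
transcription rates, and injectable outlier replicates.

Channel model per (cell line, replicate), with per-construct plasmid copy
numbers ``c_i`` drawn lognormally around equimolar and activities
``alpha_i``:

* DNA counts   ~ multinomial(depth_dna, p ∝ c_i)
* RT+ counts   ~ multinomial(depth_rtplus, p ∝ (alpha_i*g_i + kappa)*c_i)
  where g_i is a gamma(shape, mean 1) overdispersion multiplier on the
  transcriptional component only
* RT- counts   ~ Poisson(s * kappa * c_i) with s the reads-per-molecule
  scale of the RT+ library, so that raw-count background subtraction is
  unbiased (the experiment matches amplification between the two channels);
  passing an explicit ``depth_rtminus`` instead draws
  multinomial(depth_rtminus, p ∝ c_i), reproducing a fixed sequencing
  budget at the cost of a subtraction bias when the budgets are mismatched.

Under this model the expected analysis estimate of the mean log ratio for
a variant equals ln(rho_v).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from mpratag.library import (
    Construct,
    NEGATIVE_CONTROL_ID,
    POSITIVE_CONTROL_ID,
    VariantPair,
    build_constructs,
)
from mpratag.tags import ANCHOR_3P, ANCHOR_5P, SampleCounts, TagAssignment, TAG_LEN

BASES = np.array(list("ACGT"))

#: Fixed read scaffold pieces (vector / amplicon context around insert and tag).
READ_KPNI = "GGTACC"
READ_NHEI = "GCTAGC"
READ_TAG_PREFIX = "AACCATAGGATTCGCGTCAG"  # immediately precedes the 5' anchor
READ_TAIL = "GTCTGGCGTCTTGGCTAATC"  # immediately follows the 3' anchor

OUTLIER_MODES = ("high_rtminus", "low_rtplus")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the generative model; ``seed`` makes every output
    reproducible bit-for-bit."""

    n_variants: int = 25
    n_cell_lines: int = 3
    n_replicates: int = 10
    tags_per_construct: int = 1
    molar_ratio_dispersion: float = 0.3
    #: scalar rho for all variants, a sequence by variant index, or a
    #: mapping variant_id -> rho (missing entries default to 1.0)
    activity_ratios: float | Sequence[float] | Mapping[str, float] = 1.0
    baseline_activity: float = 1.0
    positive_control_activity: float = 20.0
    carryover_fraction: float = 0.05
    depth_rtplus: int = 100_000
    depth_rtminus: int | None = None  # None: RT- scale follows the carryover model
    depth_dna: int = 100_000
    overdispersion: float | None = None  # gamma shape; None disables
    read_error_rate: float = 0.0
    #: (cell_line, replicate, mode, factor) with mode high_rtminus|low_rtplus
    outlier_replicates: tuple[tuple[str, int, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 0 or self.n_cell_lines < 1 or self.n_replicates < 1:
            raise ValueError("n_variants >= 0, n_cell_lines and n_replicates >= 1")
        if self.tags_per_construct < 1:
            raise ValueError("tags_per_construct must be >= 1")
        if not 0.0 <= self.carryover_fraction <= 1.0:
            raise ValueError("carryover_fraction must lie in [0, 1]")
        for name in ("depth_rtplus", "depth_dna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth_rtminus is not None and self.depth_rtminus < 0:
            raise ValueError("depth_rtminus must be non-negative")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion (gamma shape) must be positive")
        if not 0.0 <= self.read_error_rate < 1.0:
            raise ValueError("read_error_rate must lie in [0, 1)")
        for entry in self.outlier_replicates:
            cl, rep, mode, factor = entry
            if mode not in OUTLIER_MODES:
                raise ValueError(f"outlier mode must be one of {OUTLIER_MODES}: {mode}")
            if factor <= 0:
                raise ValueError("outlier factor must be positive")

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(f"CL{i + 1}" for i in range(self.n_cell_lines))

    def rho(self, variant_ids: Sequence[str]) -> dict[str, float]:
        """Resolve ``activity_ratios`` into a per-variant mapping."""
        if isinstance(self.activity_ratios, Mapping):
            out = {v: float(self.activity_ratios.get(v, 1.0)) for v in variant_ids}
        elif isinstance(self.activity_ratios, (int, float)):
            out = {v: float(self.activity_ratios) for v in variant_ids}
        else:
            seq = list(self.activity_ratios)
            if len(seq) != len(variant_ids):
                raise ValueError(
                    f"activity_ratios sequence length {len(seq)} != n_variants "
                    f"{len(variant_ids)}"
                )
            out = {v: float(r) for v, r in zip(variant_ids, seq)}
        for v, r in out.items():
            if r <= 0:
                raise ValueError(f"activity ratio for {v} must be positive, got {r}")
        return out


@dataclass
class GroundTruth:
    """True parameters behind a simulated count set."""

    activity_ratios: dict[str, float]
    construct_activity: dict[str, float]
    #: (cell_line, replicate) -> construct_id -> plasmid copy number
    copy_numbers: dict[tuple[str, int], dict[str, float]]
    #: (cell_line, replicate) -> construct_id -> expected RNA abundance
    expected_rna: dict[tuple[str, int], dict[str, float]]
    outliers: list[tuple[str, int, str, float]] = field(default_factory=list)


Library = tuple[list[VariantPair], list[Construct], list[TagAssignment]]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def simulate_library(params: SimulationParams) -> Library:
    """Generate a variant library plus its constructs and a unique tag map.

    Variant ids are ``var001``... with random flanks and SNV allele pairs;
    each construct receives ``tags_per_construct`` distinct random 20-mers
    (collision-checked across the whole library).
    """
    rng = _rng(params.seed, 0)
    pairs: list[VariantPair] = []
    for i in range(params.n_variants):
        anc, der = rng.choice(BASES, size=2, replace=False)
        pairs.append(
            VariantPair(
                variant_id=f"var{i + 1:03d}",
                chrom=f"chr{(i % 22) + 1}",
                pos=1_000_000 + 1000 * i,
                ancestral_allele=str(anc),
                derived_allele=str(der),
                flank5=_random_dna(rng, 25),
                flank3=_random_dna(rng, 25),
                tf_name=f"TF{i + 1}",
            )
        )
    if pairs:
        constructs = build_constructs(pairs)
    else:
        constructs = [
            Construct(POSITIVE_CONTROL_ID, "positive_control", "GACATTGATTATTGACTAG"),
            Construct(NEGATIVE_CONTROL_ID, "negative_control", ""),
        ]
    assignments: list[TagAssignment] = []
    seen: set[str] = set()
    for c in constructs:
        for _ in range(params.tags_per_construct):
            for attempt in range(100):
                tag = _random_dna(rng, TAG_LEN)
                if tag not in seen and ANCHOR_5P not in tag:
                    break
            else:
                raise SimulationError("tag collision retry budget exhausted")
            seen.add(tag)
            assignments.append(
                TagAssignment(tag=tag, status="unique", construct_id=c.construct_id, support=10)
            )
    return pairs, constructs, assignments


def _construct_activities(
    pairs: list[VariantPair],
    constructs: list[Construct],
    params: SimulationParams,
    rho: dict[str, float],
) -> dict[str, float]:
    alpha: dict[str, float] = {}
    for c in constructs:
        if c.kind == "negative_control":
            alpha[c.construct_id] = params.baseline_activity
        elif c.kind == "positive_control":
            alpha[c.construct_id] = params.baseline_activity * params.positive_control_activity
        elif c.allele_state == "ancestral":
            alpha[c.construct_id] = params.baseline_activity
        else:
            alpha[c.construct_id] = params.baseline_activity * rho[c.variant_id]
    return alpha


def simulate_counts(
    library: Library, params: SimulationParams
) -> tuple[list[SampleCounts], GroundTruth]:
    """Draw RT+/RT-/DNA tag-count tables for every (cell line, replicate).

    Returns one :class:`SampleCounts` per sample (tags with zero counts
    included) and the :class:`GroundTruth` used to generate them.
    """
    pairs, constructs, assignments = library
    unique = [a for a in assignments if a.status == "unique"]
    tags = [a.tag for a in unique]
    tag_construct = [a.construct_id for a in unique]
    cids = [c.construct_id for c in constructs]
    cid_index = {cid: i for i, cid in enumerate(cids)}
    tags_per_cid = np.bincount(
        [cid_index[cid] for cid in tag_construct], minlength=len(cids)
    )
    if np.any(tags_per_cid == 0):
        missing = [cid for cid, n in zip(cids, tags_per_cid) if n == 0]
        raise SimulationError(f"constructs without tags: {missing}")

    rho = params.rho([p.variant_id for p in pairs])
    alpha_map = _construct_activities(pairs, constructs, params, rho)
    alpha = np.array([alpha_map[cid] for cid in cids])
    kappa = params.carryover_fraction

    rng = _rng(params.seed, 1)
    truth = GroundTruth(
        activity_ratios=rho,
        construct_activity=alpha_map,
        copy_numbers={},
        expected_rna={},
        outliers=list(params.outlier_replicates),
    )
    outlier_lookup = {
        (cl, rep): (mode, factor) for cl, rep, mode, factor in params.outlier_replicates
    }

    def _per_tag(construct_rates: np.ndarray) -> np.ndarray:
        per_cid = construct_rates / tags_per_cid
        return np.array([per_cid[cid_index[cid]] for cid in tag_construct])

    def _multinomial(depth: int, rates: np.ndarray) -> np.ndarray:
        total = rates.sum()
        if total <= 0 or depth <= 0:
            return np.zeros(len(rates), dtype=np.int64)
        return rng.multinomial(depth, rates / total)

    samples: list[SampleCounts] = []
    for cl in params.cell_lines:
        for rep in range(1, params.n_replicates + 1):
            copies = np.exp(
                rng.normal(0.0, params.molar_ratio_dispersion, size=len(cids))
            )
            if params.overdispersion is not None:
                g = rng.gamma(
                    params.overdispersion, 1.0 / params.overdispersion, size=len(cids)
                )
            else:
                g = np.ones(len(cids))

            dna = _multinomial(params.depth_dna, _per_tag(copies))
            rtplus_rates = (alpha * g + kappa) * copies
            rtplus = _multinomial(params.depth_rtplus, _per_tag(rtplus_rates))
            if params.depth_rtminus is not None:
                rtminus = _multinomial(
                    params.depth_rtminus,
                    _per_tag(copies) if kappa > 0 else np.zeros(len(tags)),
                )
            else:
                # reads-per-molecule scale of the RT+ library carried over to
                # the RT- library: raw-count subtraction stays unbiased
                s = params.depth_rtplus / rtplus_rates.sum()
                rtminus = rng.poisson(s * kappa * _per_tag(copies)).astype(np.int64)

            mode_factor = outlier_lookup.get((cl, rep))
            if mode_factor is not None:
                mode, factor = mode_factor
                if mode == "high_rtminus":
                    rtminus = np.round(rtminus * factor).astype(np.int64)
                else:  # low_rtplus
                    rtplus = np.round(rtplus / factor).astype(np.int64)

            key = (cl, rep)
            truth.copy_numbers[key] = dict(zip(cids, copies.tolist()))
            truth.expected_rna[key] = dict(
                zip(cids, (alpha * g * copies).tolist())
            )
            for assay, vec in (("RTplus", rtplus), ("RTminus", rtminus), ("DNA", dna)):
                samples.append(
                    SampleCounts(
                        cell_line=cl,
                        replicate=rep,
                        assay=assay,
                        counts={t: int(n) for t, n in zip(tags, vec)},
                    )
                )
    return samples, truth


def _read_for_tag(insert: str, tag: str) -> str:
    if insert:
        body = READ_KPNI + insert + READ_NHEI
    else:
        body = READ_KPNI + READ_NHEI  # insert-less backbone junction
    return body + READ_TAG_PREFIX + ANCHOR_5P + tag + ANCHOR_3P + READ_TAIL


def simulate_reads(
    library: Library,
    counts: SampleCounts | Iterable[SampleCounts],
    params: SimulationParams,
) -> Iterator[str]:
    """Emit one read per counted tag occurrence.

    Reads carry the construct insert (flanked by its cloning sites), the
    fixed tag scaffold, and the tag itself, so they serve both for
    tag-construct association and for tag counting.  A uniform per-base
    substitution error is applied at ``params.read_error_rate``.
    """
    _, constructs, assignments = library
    insert_by_cid = {c.construct_id: c.insert_sequence for c in constructs}
    tag_to_cid = {a.tag: a.construct_id for a in assignments if a.status == "unique"}
    rng = _rng(params.seed, 2)
    if isinstance(counts, SampleCounts):
        count_list = [counts]
    else:
        count_list = list(counts)
    for sample in count_list:
        for tag in sorted(sample.counts):
            cid = tag_to_cid.get(tag)
            if cid is None:
                raise SimulationError(f"count table contains unknown tag {tag}")
            read = _read_for_tag(insert_by_cid[cid], tag)
            for _ in range(sample.counts[tag]):
                if params.read_error_rate > 0:
                    yield _mutate(read, params.read_error_rate, rng)
                else:
                    yield read


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(read))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def null_params(**overrides) -> SimulationParams:
    """Convenience: parameters with all true activity ratios at 1."""
    return replace(SimulationParams(), **overrides)
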