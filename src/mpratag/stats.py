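"""Normalized log-ratio activity statistics for tag-count reporter assays.

The per-replicate activity statistic for a derived/ancestral allele pair is

    ln( ((d_RT+ - d_RT-) / (a_RT+ - a_RT-)) / (d_DNA / a_DNA) )

i.e. the RT-minus background is subtracted from each allele's RT-plus tag
count, the derived/ancestral RNA ratio is formed, and that ratio is divided
by the corresponding plasmid-DNA ratio to correct for molar-ratio
differences of the constructs in the cells.  The same statistic with the
negative control in the denominator measures activity relative to the
insert-less backbone.

Per variant and cell line, valid replicate values are tested against 0 with
a one-sample two-sided t-test; p-values are Benjamini-Hochberg adjusted
within each cell line (separately per comparison family by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from mpratag.library import Construct, NEGATIVE_CONTROL_ID

COMPARISON_DA = "derived_vs_ancestral"
COMPARISON_NC = "variant_vs_negcontrol"

QC_EXCLUDED = "qc_excluded"
NONPOSITIVE = "nonpositive_after_subtraction"
ZERO_DENOM = "zero_denominator"


class AnalysisError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReplicateLogRatio:
    """Per-replicate normalized log ratio with validity flag.

    ``variant_id`` holds the variant label for derived-vs-ancestral
    comparisons and the allele construct id for vs-negative-control
    comparisons.
    """

    variant_id: str
    cell_line: str
    replicate: int
    comparison: str
    value: float
    valid: bool
    invalid_reason: str | None = None

    def __post_init__(self) -> None:
        if self.valid != math.isfinite(self.value):
            raise ValueError("value is finite iff valid")
        if self.valid and self.invalid_reason is not None:
            raise ValueError("valid results carry no invalid_reason")


@dataclass(frozen=True)
class ActivityTestResult:
    """One variant x cell line x comparison test result.

    ``variant_id`` holds the construct id for the vs-negative-control
    family.  ``note`` is "" for a regular test, "untestable" when fewer
    than two valid replicates were available, "degenerate" when the
    replicate values had zero variance.
    """

    variant_id: str
    cell_line: str
    comparison: str
    n_valid_replicates: int
    mean_log_ratio: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    q_value: float
    significant: bool
    signed_fold_change: float
    note: str = ""


def _validate_counts(*counts: float) -> None:
    for c in counts:
        if c < 0:
            raise ValueError(f"negative count: {c}")


def _log_ratio(
    num_rtplus: float,
    num_rtminus: float,
    den_rtplus: float,
    den_rtminus: float,
    num_dna: float,
    den_dna: float,
) -> tuple[float, str | None]:
    _validate_counts(num_rtplus, num_rtminus, den_rtplus, den_rtminus, num_dna, den_dna)
    if num_dna == 0 or den_dna == 0:
        return math.nan, ZERO_DENOM
    num_rna = num_rtplus - num_rtminus
    den_rna = den_rtplus - den_rtminus
    if num_rna <= 0 or den_rna <= 0:
        return math.nan, NONPOSITIVE
    # cross-products + canonical ordering keep antisymmetry (d<->a swap
    # negates exactly) and depth scaling (common factors cancel exactly)
    # bit-exact for integer counts
    p = num_rna * den_dna
    q = den_rna * num_dna
    value = math.log(p / q) if p >= q else -math.log(q / p)
    return value, None


def replicate_log_ratio(
    d_rtplus: float,
    d_rtminus: float,
    a_rtplus: float,
    a_rtminus: float,
    d_dna: float,
    a_dna: float,
    *,
    variant_id: str = "",
    cell_line: str = "",
    replicate: int = 0,
) -> ReplicateLogRatio:
    """Normalized log ratio of derived over ancestral tag counts for one
    replicate.

    Invalid (non-finite) outcomes are flagged rather than raised: a
    background-subtracted RNA count <= 0 gives ``nonpositive_after_
    subtraction``; a zero DNA count on either side gives
    ``zero_denominator``.  Negative raw counts are a contract violation.
    """
    value, reason = _log_ratio(d_rtplus, d_rtminus, a_rtplus, a_rtminus, d_dna, a_dna)
    return ReplicateLogRatio(
        variant_id=variant_id,
        cell_line=cell_line,
        replicate=replicate,
        comparison=COMPARISON_DA,
        value=value,
        valid=reason is None,
        invalid_reason=reason,
    )


def negcontrol_log_ratio(
    v_rtplus: float,
    v_rtminus: float,
    n_rtplus: float,
    n_rtminus: float,
    v_dna: float,
    n_dna: float,
    *,
    construct_id: str = "",
    cell_line: str = "",
    replicate: int = 0,
) -> ReplicateLogRatio:
    """Log ratio of one allele construct over the negative control;
    identical contract to :func:`replicate_log_ratio`."""
    value, reason = _log_ratio(v_rtplus, v_rtminus, n_rtplus, n_rtminus, v_dna, n_dna)
    return ReplicateLogRatio(
        variant_id=construct_id,
        cell_line=cell_line,
        replicate=replicate,
        comparison=COMPARISON_NC,
        value=value,
        valid=reason is None,
        invalid_reason=reason,
    )


def qc_flag_replicates(
    rtplus_norm: Mapping[int, float],
    rtminus_norm: Mapping[int, float],
    *,
    k: float = 3.0,
    external_exclusions: Iterable[int] = (),
    min_replicates: int = 4,
) -> dict[int, bool]:
    """Flag outlier replicates for one construct in one cell line.

    Inputs are depth-normalized counts (count / sample total) per
    replicate.  Replicate ``r`` is excluded when its RT-minus value exceeds
    median + k*MAD of the *other* replicates, or its RT-plus value falls
    below median - k*MAD of the others (one-sided each).  Entries in
    ``external_exclusions`` are excluded unconditionally.

    Returns ``{replicate: valid}``.  With fewer than ``min_replicates``
    replicates no automatic flagging is performed (a warning is emitted);
    external exclusions still apply.
    """
    reps = sorted(set(rtplus_norm) | set(rtminus_norm))
    external = set(external_exclusions)
    valid = {r: r not in external for r in reps}
    if len(reps) < min_replicates:
        if reps:
            warnings.warn(
                f"only {len(reps)} replicates: outlier flagging skipped",
                stacklevel=2,
            )
        return valid

    # R mad(): median absolute deviation with the 1.4826 normal-consistency
    # constant, so k*MAD reads in sigma units
    def _median_mad(values: Sequence[float]) -> tuple[float, float]:
        med = float(np.median(values))
        mad = 1.4826 * float(np.median(np.abs(np.asarray(values) - med)))
        return med, mad

    for r in reps:
        others = [x for x in reps if x != r]
        minus_others = [rtminus_norm.get(x, 0.0) for x in others]
        med_m, mad_m = _median_mad(minus_others)
        if rtminus_norm.get(r, 0.0) > med_m + k * mad_m:
            valid[r] = False
            continue
        plus_others = [rtplus_norm.get(x, 0.0) for x in others]
        med_p, mad_p = _median_mad(plus_others)
        if rtplus_norm.get(r, 0.0) < med_p - k * mad_p:
            valid[r] = False
    return valid


@dataclass(frozen=True)
class TTestOutcome:
    t: float
    df: int
    p: float
    note: str = ""  # "" | untestable | degenerate


def one_sample_t_test(values: Sequence[float]) -> TTestOutcome:
    """Two-sided one-sample t-test of mean = 0.

    Degenerate inputs are flagged instead of raised: fewer than two values
    -> untestable (NaN statistics); zero variance with nonzero mean -> p=0
    with a degeneracy note; zero variance with zero mean -> p=1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    n = arr.size
    if n < 2:
        return TTestOutcome(t=math.nan, df=n - 1, p=math.nan, note="untestable")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestOutcome(t=0.0, df=df, p=1.0, note="degenerate")
        return TTestOutcome(
            t=math.copysign(math.inf, mean), df=df, p=0.0, note="degenerate"
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestOutcome(t=t, df=df, p=p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (R p.adjust BH)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def signed_fold_change(mean_log_ratio: float) -> float:
    """Convert a mean natural-log ratio to a signed fold change.

    Positive ratios map to exp(m) >= 1; negative ratios map to -exp(-m)
    <= -1, so the scale has no values between +1 and -1 and both +1 and -1
    mean "no difference".
    """
    if not math.isfinite(mean_log_ratio):
        raise ValueError("mean_log_ratio must be finite")
    if mean_log_ratio >= 0:
        return math.exp(mean_log_ratio)
    return -math.exp(-mean_log_ratio)


def cell_line_correlations(
    mean_ratios: pd.DataFrame, *, min_overlap: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-variant mean log ratios.

    ``mean_ratios`` has one row per variant and one column per cell line
    (NaN for missing means).  Returns one row per unordered cell-line pair
    with columns cell_line_a, cell_line_b, r, n, note; pairs with fewer
    than ``min_overlap`` shared variants or zero variance are flagged with
    r = NaN.
    """
    cell_lines = list(mean_ratios.columns)
    rows = []
    for i, ca in enumerate(cell_lines):
        for cb in cell_lines[i + 1 :]:
            sub = mean_ratios[[ca, cb]].dropna()
            n = len(sub)
            if n < min_overlap:
                rows.append((ca, cb, math.nan, n, "insufficient_overlap"))
                continue
            x, y = sub[ca].to_numpy(), sub[cb].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((ca, cb, math.nan, n, "zero_variance"))
                continue
            r = float(sps.pearsonr(x, y).statistic)
            rows.append((ca, cb, r, n, ""))
    return pd.DataFrame(rows, columns=["cell_line_a", "cell_line_b", "r", "n", "note"])


def classify_variants(results: Sequence[ActivityTestResult]) -> pd.DataFrame:
    """Per-variant summary of significant calls across cell lines.

    For each variant: the number of cell lines where the derived allele
    differs significantly from the ancestral (split by direction), and the
    number of cell lines where either allele is significantly above
    (enhancer-like) or below (repressor-like) the negative control.
    """
    da = [r for r in results if r.comparison == COMPARISON_DA]
    nc = [r for r in results if r.comparison == COMPARISON_NC]

    def _variant_of_construct(cid: str) -> str:
        return cid.rsplit("|", 1)[0]

    variants = sorted(
        {r.variant_id for r in da} | {_variant_of_construct(r.variant_id) for r in nc}
    )
    rows = []
    for v in variants:
        da_v = [r for r in da if r.variant_id == v and r.significant]
        up = {r.cell_line for r in da_v if r.mean_log_ratio > 0}
        down = {r.cell_line for r in da_v if r.mean_log_ratio < 0}
        nc_v = [
            r for r in nc if _variant_of_construct(r.variant_id) == v and r.significant
        ]
        enh = {r.cell_line for r in nc_v if r.mean_log_ratio > 0}
        rep = {r.cell_line for r in nc_v if r.mean_log_ratio < 0}
        rows.append(
            (
                v,
                len(up | down),
                len(up),
                len(down),
                len(enh),
                len(rep),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "n_cell_lines_allelic_significant",
            "n_cell_lines_derived_up",
            "n_cell_lines_derived_down",
            "n_cell_lines_enhancer",
            "n_cell_lines_repressor",
        ],
    )


# ---------------------------------------------------------------------------
# Dataset-level orchestration


@dataclass
class AnalysisResult:
    replicate_ratios: pd.DataFrame
    results_da: pd.DataFrame
    results_nc: pd.DataFrame
    correlations: pd.DataFrame
    classification: pd.DataFrame
    qc_flags: pd.DataFrame
    messages: list[str] = field(default_factory=list)

    def all_results(self) -> list[ActivityTestResult]:
        out = []
        for df in (self.results_da, self.results_nc):
            for rec in df.itertuples(index=False):
                out.append(
                    ActivityTestResult(
                        variant_id=rec.variant_id,
                        cell_line=rec.cell_line,
                        comparison=rec.comparison,
                        n_valid_replicates=int(rec.n_valid),
                        mean_log_ratio=float(rec.mean_log_ratio),
                        t_statistic=float(rec.t),
                        degrees_of_freedom=int(rec.df),
                        p_value=float(rec.p),
                        q_value=float(rec.q),
                        significant=bool(rec.significant),
                        signed_fold_change=float(rec.signed_fold_change),
                        note=rec.note,
                    )
                )
        return out


REQUIRED_COUNT_COLUMNS = ("cell_line", "replicate", "assay", "construct_id", "count")


def _check_complete(counts: pd.DataFrame) -> None:
    have = {
        (cl, int(rep)): set(g["assay"])
        for (cl, rep), g in counts.groupby(["cell_line", "replicate"])
    }
    for (cl, rep), assays in sorted(have.items()):
        missing = {"RTplus", "RTminus", "DNA"} - assays
        if missing:
            raise AnalysisError(
                f"missing assay(s) {sorted(missing)} for cell line {cl} replicate {rep}"
            )


def _test_family(ratios: list[ReplicateLogRatio]) -> pd.DataFrame:
    """t-test each (unit, cell line) group of replicate ratios."""
    rows = []
    groups: dict[tuple[str, str, str], list[ReplicateLogRatio]] = {}
    for r in ratios:
        groups.setdefault((r.variant_id, r.cell_line, r.comparison), []).append(r)
    for (unit, cl, comparison), items in sorted(groups.items()):
        values = [r.value for r in items if r.valid]
        outcome = one_sample_t_test(values)
        mean = float(np.mean(values)) if values else math.nan
        sfc = signed_fold_change(mean) if math.isfinite(mean) else math.nan
        rows.append(
            {
                "variant_id": unit,
                "cell_line": cl,
                "comparison": comparison,
                "n_valid": len(values),
                "mean_log_ratio": mean,
                "t": outcome.t,
                "df": outcome.df,
                "p": outcome.p,
                "q": math.nan,
                "significant": False,
                "signed_fold_change": sfc,
                "note": outcome.note,
            }
        )
    return pd.DataFrame(rows)


def _apply_bh(df: pd.DataFrame, alpha: float, family_cols: list[str]) -> pd.DataFrame:
    """BH-adjust p-values within each family defined by ``family_cols``."""
    if df.empty:
        return df
    df = df.copy()
    for _, idx in df.groupby(family_cols).groups.items():
        sub = df.loc[idx]
        testable = sub.index[np.isfinite(sub["p"])]
        if len(testable) == 0:
            continue
        q = bh_adjust(df.loc[testable, "p"].to_numpy())
        df.loc[testable, "q"] = q
        df.loc[testable, "significant"] = q < alpha
    return df


def analyze_dataset(
    counts: pd.DataFrame,
    constructs: list[Construct],
    *,
    alpha: float = 0.05,
    qc_k: float = 3.0,
    bh_family_mode: str = "separate",
    external_exclusions: Iterable[tuple[str, int, str | None]] = (),
) -> AnalysisResult:
    """Run the full statistical analysis on construct-aggregated counts.

    ``counts`` columns: cell_line, replicate, assay, construct_id, count.
    ``external_exclusions`` entries are (cell_line, replicate,
    construct_id or None); None applies to every construct in that
    replicate.  ``bh_family_mode`` is "separate" (default: allelic and
    vs-negative-control tests corrected in separate per-cell-line families)
    or "combined" (one family per cell line).
    """
    if bh_family_mode not in ("separate", "combined"):
        raise ValueError(f"bh_family_mode must be separate|combined: {bh_family_mode!r}")
    missing_cols = set(REQUIRED_COUNT_COLUMNS) - set(counts.columns)
    if missing_cols:
        raise AnalysisError(f"count table missing columns {sorted(missing_cols)}")
    counts = counts.copy()
    counts["replicate"] = counts["replicate"].astype(int)
    counts["count"] = counts["count"].astype(np.int64)
    if (counts["count"] < 0).any():
        raise AnalysisError("negative counts in input")
    _check_complete(counts)
    messages: list[str] = []

    by_construct = {c.construct_id: c for c in constructs}
    if NEGATIVE_CONTROL_ID not in by_construct:
        raise AnalysisError("construct set lacks a negative control")
    variant_constructs = [c for c in constructs if c.kind == "variant_allele"]
    variants: dict[str, dict[str, str]] = {}
    for c in variant_constructs:
        variants.setdefault(c.variant_id, {})[c.allele_state] = c.construct_id
    for vid, alleles in variants.items():
        if set(alleles) != {"ancestral", "derived"}:
            raise AnalysisError(f"variant {vid} lacks one of its two allele constructs")

    # count lookup and per-sample totals for depth normalization
    table = counts.set_index(["cell_line", "replicate", "assay", "construct_id"])[
        "count"
    ]
    if not table.index.is_unique:
        raise AnalysisError("duplicate (cell_line, replicate, assay, construct_id) rows")
    # depth normalization for QC: one transfection replicate (cell line x
    # replicate, all three assay libraries) is the unit whose total scales
    # counts, so a channel-wide artifact stays visible while overall
    # sequencing-depth variation cancels
    totals = counts.groupby(["cell_line", "replicate"])["count"].sum()

    def _get(cl: str, rep: int, assay: str, cid: str) -> int:
        return int(table.get((cl, rep, assay, cid), 0))

    def _norm(cl: str, rep: int, assay: str, cid: str) -> float:
        tot = int(totals.get((cl, rep), 0))
        return _get(cl, rep, assay, cid) / tot if tot else 0.0

    cell_lines = sorted(counts["cell_line"].unique())
    reps_by_cl = {
        cl: sorted(counts.loc[counts["cell_line"] == cl, "replicate"].unique())
        for cl in cell_lines
    }

    external_all: dict[tuple[str, int], bool] = {}
    external_specific: set[tuple[str, int, str]] = set()
    for cl, rep, cid in external_exclusions:
        if cid is None:
            external_all[(cl, int(rep))] = True
        else:
            external_specific.add((cl, int(rep), cid))

    # QC flags per (cell line, construct, replicate)
    analyzed_cids = sorted(
        {c.construct_id for c in variant_constructs} | {NEGATIVE_CONTROL_ID}
    )
    flagged: set[tuple[str, str, int]] = set()  # (cell_line, construct_id, replicate)
    qc_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # low-replicate warning handled via messages
        for cl in cell_lines:
            reps = reps_by_cl[cl]
            if len(reps) < 4:
                messages.append(
                    f"{cl}: only {len(reps)} replicates, automatic QC flagging skipped"
                )
            for cid in analyzed_cids:
                ext = [
                    r
                    for r in reps
                    if (cl, r) in external_all or (cl, r, cid) in external_specific
                ]
                valid = qc_flag_replicates(
                    {r: _norm(cl, r, "RTplus", cid) for r in reps},
                    {r: _norm(cl, r, "RTminus", cid) for r in reps},
                    k=qc_k,
                    external_exclusions=ext,
                )
                for r, ok in valid.items():
                    if not ok:
                        flagged.add((cl, cid, r))
                        qc_rows.append(
                            {
                                "cell_line": cl,
                                "construct_id": cid,
                                "replicate": r,
                                "external": r in ext,
                            }
                        )
    qc_flags = pd.DataFrame(qc_rows, columns=["cell_line", "construct_id", "replicate", "external"])

    def _ratio_or_qc(
        unit: str,
        comparison: str,
        cl: str,
        rep: int,
        num_cid: str,
        den_cid: str,
    ) -> ReplicateLogRatio:
        if (cl, num_cid, rep) in flagged or (cl, den_cid, rep) in flagged:
            return ReplicateLogRatio(
                variant_id=unit,
                cell_line=cl,
                replicate=rep,
                comparison=comparison,
                value=math.nan,
                valid=False,
                invalid_reason=QC_EXCLUDED,
            )
        value, reason = _log_ratio(
            _get(cl, rep, "RTplus", num_cid),
            _get(cl, rep, "RTminus", num_cid),
            _get(cl, rep, "RTplus", den_cid),
            _get(cl, rep, "RTminus", den_cid),
            _get(cl, rep, "DNA", num_cid),
            _get(cl, rep, "DNA", den_cid),
        )
        return ReplicateLogRatio(
            variant_id=unit,
            cell_line=cl,
            replicate=rep,
            comparison=comparison,
            value=value,
            valid=reason is None,
            invalid_reason=reason,
        )

    ratios_da: list[ReplicateLogRatio] = []
    ratios_nc: list[ReplicateLogRatio] = []
    for cl in cell_lines:
        for rep in reps_by_cl[cl]:
            for vid in sorted(variants):
                d_cid = variants[vid]["derived"]
                a_cid = variants[vid]["ancestral"]
                ratios_da.append(
                    _ratio_or_qc(vid, COMPARISON_DA, cl, rep, d_cid, a_cid)
                )
                for cid in (a_cid, d_cid):
                    ratios_nc.append(
                        _ratio_or_qc(
                            cid, COMPARISON_NC, cl, rep, cid, NEGATIVE_CONTROL_ID
                        )
                    )

    results_da = _test_family(ratios_da)
    results_nc = _test_family(ratios_nc)
    if bh_family_mode == "separate":
        results_da = _apply_bh(results_da, alpha, ["cell_line"])
        results_nc = _apply_bh(results_nc, alpha, ["cell_line"])
    else:
        combined = pd.concat([results_da, results_nc], ignore_index=True)
        combined = _apply_bh(combined, alpha, ["cell_line"])
        results_da = combined[combined["comparison"] == COMPARISON_DA].reset_index(
            drop=True
        )
        results_nc = combined[combined["comparison"] == COMPARISON_NC].reset_index(
            drop=True
        )

    for df in (results_da, results_nc):
        for rec in df[df["note"] == "untestable"].itertuples(index=False):
            messages.append(
                f"{rec.variant_id} in {rec.cell_line}: untestable "
                f"({rec.n_valid} valid replicates)"
            )

    mean_matrix = results_da.pivot(
        index="variant_id", columns="cell_line", values="mean_log_ratio"
    )
    correlations = cell_line_correlations(mean_matrix)

    rep_rows = [
        {
            "variant_id": r.variant_id,
            "cell_line": r.cell_line,
            "replicate": r.replicate,
            "comparison": r.comparison,
            "value": r.value,
            "valid": r.valid,
            "invalid_reason": r.invalid_reason or "",
        }
        for r in ratios_da + ratios_nc
    ]
    replicate_ratios = pd.DataFrame(rep_rows)

    result = AnalysisResult(
        replicate_ratios=replicate_ratios,
        results_da=results_da,
        results_nc=results_nc,
        correlations=correlations,
        classification=pd.DataFrame(),
        qc_flags=qc_flags,
        messages=messages,
    )
    result.classification = classify_variants(result.all_results())
    return result
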