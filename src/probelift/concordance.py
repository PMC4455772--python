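"""Agreement between array beta values and bisulfite methylation ratios at
shared CpGs.

Pairs are formed per (probe, sample) wherever the probe's projected target
CpG coincides with a sequencing call (calls landing on the G of the CpG are
folded onto the C).  Summaries report Pearson correlation and the fraction
of pairs whose two measurements agree within 0.20 / 0.10 / 0.05 (inclusive,
on the 0-1 methylation scale), overall and per stratum: bitscore bin,
uniqueness, mismatch category, probe type, mean-methylation tier.

By default the correlation is computed per sample and averaged (unweighted)
across samples; ``per_sample=False`` pools all pairs instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filters import ProbeAnnotationRecord
from .io_formats import BetaMatrix, MethylationCall

#: default bitscore stratification cut set: <=70, (70, 80], >80
BITSCORE_BINS = (70.0, 80.0)

ERROR_BINS = (0.20, 0.10, 0.05)

STRATA_COLUMNS = ("bitscore_bin", "unique", "mismatch_category", "probe_type", "meth_tier")


def bitscore_bin(b: float, cuts: tuple[float, float] = BITSCORE_BINS) -> str:
    lo, hi = cuts
    if b <= lo:
        return f"<={lo:g}"
    if b <= hi:
        return f"{lo:g}-{hi:g}"
    return f">{hi:g}"


def meth_tier(mean_meth: float) -> str:
    """Mean-methylation tier: low < 0.3, mid in [0.3, 0.7], high > 0.7."""
    if mean_meth < 0.3:
        return "low"
    if mean_meth <= 0.7:
        return "mid"
    return "high"


# ---------------------------------------------------------------------------
# joining


def join_shared(
    annot: list[ProbeAnnotationRecord],
    betas: BetaMatrix,
    meth: dict[str, list[MethylationCall]],
    bitscore_cuts: tuple[float, float] = BITSCORE_BINS,
) -> pd.DataFrame:
    """Pair probes with sequencing calls at shared CpGs.

    ``meth`` maps sample_id -> coverage-filtered calls (1-based + strand C
    positions).  A call at the G of a CpG (C position + 1) folds onto the C.
    Returns one row per (probe, sample) with a non-missing beta, carrying
    the stratification keys from the annotation.
    """
    call_maps: dict[str, dict[tuple[str, int], MethylationCall]] = {}
    for sample, calls in meth.items():
        m: dict[tuple[str, int], MethylationCall] = {}
        for c in calls:
            m.setdefault((c.chrom, c.pos), c)
        call_maps[sample] = m

    rows = []
    for rec in annot:
        if not rec.mapped or rec.target_cpg_pos is None:
            continue
        if rec.probe_id not in betas.beta.index:
            continue
        c_pos_1based = rec.target_cpg_pos + 1
        beta_row = betas.beta.loc[rec.probe_id]
        for sample, cmap in call_maps.items():
            call = cmap.get((rec.contig, c_pos_1based))
            if call is None:
                # fold a G-strand call back onto the C of the dinucleotide
                call = cmap.get((rec.contig, c_pos_1based + 1))
            if call is None:
                continue
            beta = beta_row.get(sample, np.nan)
            if beta is None or (isinstance(beta, float) and math.isnan(beta)):
                continue
            ratio = call.ratio
            mean = (beta + ratio) / 2.0
            rows.append(
                {
                    "probe_id": rec.probe_id,
                    "sample_id": sample,
                    "beta": float(beta),
                    "seq_ratio": ratio,
                    "coverage": call.total_count,
                    "mean_meth": mean,
                    "diff": ratio - float(beta),
                    "bitscore": rec.bitscore,
                    "bitscore_bin": bitscore_bin(rec.bitscore, bitscore_cuts),
                    "unique": rec.unique,
                    "mismatch_category": rec.mismatch_category,
                    "probe_type": rec.probe_type,
                    "meth_tier": meth_tier(mean),
                    "pass_all": rec.pass_all,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "sample_id",
            "beta",
            "seq_ratio",
            "coverage",
            "mean_meth",
            "diff",
            "bitscore",
            "bitscore_bin",
            "unique",
            "mismatch_category",
            "probe_type",
            "meth_tier",
            "pass_all",
        ],
    )


# ---------------------------------------------------------------------------
# summaries


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN marks 'undefined' (n < 2 or zero variance)."""
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def _group_metrics(g: pd.DataFrame, per_sample: bool) -> dict:
    n = len(g)
    absdiff = g["diff"].abs().to_numpy()
    out = {
        "n_pairs": n,
        "pct_within_20": 100.0 * float(np.mean(absdiff <= ERROR_BINS[0])) if n else math.nan,
        "pct_within_10": 100.0 * float(np.mean(absdiff <= ERROR_BINS[1])) if n else math.nan,
        "pct_within_5": 100.0 * float(np.mean(absdiff <= ERROR_BINS[2])) if n else math.nan,
    }
    if per_sample:
        rs = [
            _pearson(s["beta"].to_numpy(), s["seq_ratio"].to_numpy())
            for _, s in g.groupby("sample_id")
        ]
        rs = [r for r in rs if not math.isnan(r)]
        out["pearson_r"] = float(np.mean(rs)) if rs else math.nan
    else:
        out["pearson_r"] = _pearson(g["beta"].to_numpy(), g["seq_ratio"].to_numpy())
    return out


def summarize(
    pairs: pd.DataFrame,
    strata: list[str] | None = None,
    per_sample: bool = True,
) -> pd.DataFrame:
    """Concordance metrics pooled and per stratum.

    Returns a tidy frame with columns (stratum, level, n_pairs, pearson_r,
    pct_within_20, pct_within_10, pct_within_5); the pooled row has stratum
    'all'.  A NaN pearson_r marks an undefined correlation (fewer than two
    pairs or zero variance), never a propagated computation error.
    """
    strata = list(STRATA_COLUMNS) if strata is None else strata
    rows = [{"stratum": "all", "level": "all", **_group_metrics(pairs, per_sample)}]
    for key in strata:
        if key not in pairs.columns:
            raise KeyError(f"unknown stratification key {key!r}")
        for level, g in pairs.groupby(key, sort=True):
            rows.append(
                {"stratum": key, "level": str(level), **_group_metrics(g, per_sample)}
            )
    return pd.DataFrame(rows)


def bland_altman(pairs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Bland-Altman table: per pair (mean_meth, diff) with diff defined as
    sequencing minus array; stats hold the mean difference and the 1.96*sd
    limits of agreement."""
    table = pairs[["probe_id", "sample_id", "mean_meth", "diff"]].copy()
    diffs = pairs["diff"].to_numpy(dtype=float)
    mean_diff = float(np.mean(diffs)) if diffs.size else math.nan
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    stats_d = {
        "mean_diff": mean_diff,
        "loa_lower": mean_diff - 1.96 * sd,
        "loa_upper": mean_diff + 1.96 * sd,
        "n": int(diffs.size),
    }
    return table, stats_d


def delta_concordance(pairs: pd.DataFrame) -> dict:
    """Cross-platform agreement of inter-individual differences.

    For every probe measured on both platforms in >= 2 samples and every
    unordered sample pair, compares the array delta (beta_i - beta_j) with
    the sequencing delta (ratio_i - ratio_j); reports the percent of
    observations with |delta_array - delta_seq| within 0.20/0.10/0.05.
    """
    devs: list[float] = []
    for _, g in pairs.groupby("probe_id"):
        by_sample = g.set_index("sample_id")
        samples = sorted(by_sample.index.unique())
        for si, sj in itertools.combinations(samples, 2):
            d_arr = by_sample.at[si, "beta"] - by_sample.at[sj, "beta"]
            d_seq = by_sample.at[si, "seq_ratio"] - by_sample.at[sj, "seq_ratio"]
            devs.append(abs(d_arr - d_seq))
    arr = np.asarray(devs, dtype=float)
    n = arr.size
    return {
        "n_observations": int(n),
        "pct_within_20": 100.0 * float(np.mean(arr <= 0.20)) if n else math.nan,
        "pct_within_10": 100.0 * float(np.mean(arr <= 0.10)) if n else math.nan,
        "pct_within_5": 100.0 * float(np.mean(arr <= 0.05)) if n else math.nan,
    }


def detection_alignment_correlation(
    annot: list[ProbeAnnotationRecord],
    betas: BetaMatrix,
    exclude_near_cpg: bool = False,
) -> pd.DataFrame:
    """Per-sample Spearman rank correlation between detection p-values and
    alignment quality (e-value, percent identity, bitscore) over mapped
    probes; optionally drops near-CpG-mismatch probes first.

    Ties get average ranks (scipy); zero-variance inputs yield NaN rho as
    the undefined marker.
    """
    if betas.detection_p is None:
        raise ValueError("beta matrix has no detection p-values")
    recs = [r for r in annot if r.mapped]
    if exclude_near_cpg:
        recs = [r for r in recs if not r.near_cpg_mismatch]
    recs = [r for r in recs if r.probe_id in betas.detection_p.index]
    metrics = {
        "evalue": np.array([r.evalue for r in recs]),
        "percent_identity": np.array([r.percent_identity for r in recs]),
        "bitscore": np.array([r.bitscore for r in recs]),
    }
    probe_ids = [r.probe_id for r in recs]
    rows = []
    for sample in betas.sample_ids:
        p = betas.detection_p.loc[probe_ids, sample].to_numpy(dtype=float)
        row = {"sample_id": sample, "n": len(probe_ids)}
        for name, vals in metrics.items():
            ok = np.isfinite(p) & np.isfinite(vals)
            if ok.sum() < 2 or np.std(p[ok]) == 0 or np.std(vals[ok]) == 0:
                row[f"rho_{name}"] = math.nan
            else:
                row[f"rho_{name}"] = float(stats.spearmanr(p[ok], vals[ok]).statistic)
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "BITSCORE_BINS",
    "ERROR_BINS",
    "STRATA_COLUMNS",
    "bitscore_bin",
    "meth_tier",
    "join_shared",
    "summarize",
    "bland_altman",
    "delta_concordance",
    "detection_alignment_correlation",
]
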