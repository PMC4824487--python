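"""qPCR / TaqMan quantification layer.

Covers the four quantitative assays downstream of sequencing:

* TaqMan allelic-discrimination calibration — ordinary least squares of
  log2(VIC/FAM intensity) on log2 of the known allelic odds from defined
  G:T mixes (50:50 ... 90:10), and its inversion to convert an observed
  VIC/FAM ratio into an allelic proportion;
* allele-specific binding tests — paired t on log2 VIC/FAM between
  immunoprecipitated (IP) and input chromatin;
* ChIP-qPCR enrichment — 2^-(Ct_IP - Ct_input) per region, normalized by the
  negative-control region;
* expression fold change — per-replicate 2^-(Ct_gene - Ct_normalizer),
  treated / vehicle fold, one-sample t-test on log2 folds.

qPCR efficiency is fixed at 2 (no efficiency correction): one cycle = one
doubling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imbalance_stats import TestResult, _t_one_sample


@dataclass
class StandardCurve:
    """Linear fit log2(VIC/FAM) = intercept + slope * log2(p / (1 - p))."""

    slope: float
    intercept: float
    r_squared: float
    calibration_points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.slope == 0.0:
            raise ValueError("standard curve slope is zero; curve is not invertible")


def fit_standard_curve(mixes: list[tuple[float, float]]) -> StandardCurve:
    """OLS fit of observed log2 VIC/FAM on log2 allelic odds of known mixes.

    ``mixes`` holds (proportion of the VIC-dye allele, observed VIC/FAM
    intensity ratio). At least two distinct proportions are required.
    """
    if len(mixes) < 2:
        raise ValueError("need at least 2 calibration mixes")
    props = np.array([m[0] for m in mixes], dtype=float)
    obs = np.array([m[1] for m in mixes], dtype=float)
    if np.any((props <= 0) | (props >= 1)):
        raise ValueError("mix proportions must be in (0, 1)")
    if np.any(obs <= 0):
        raise ValueError("observed VIC/FAM ratios must be positive")
    x = np.log2(props / (1.0 - props))
    if np.allclose(x, x[0]):
        raise ValueError("all calibration proportions identical; cannot fit a slope")
    y = np.log2(obs)
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        calibration_points=list(zip(props.tolist(), y.tolist())),
    )


def invert_standard_curve(curve: StandardCurve, vic_fam: float) -> float:
    """Convert an observed VIC/FAM intensity ratio into an allelic proportion."""
    if vic_fam <= 0:
        raise ValueError("VIC/FAM ratio must be positive")
    log2_odds = (math.log2(vic_fam) - curve.intercept) / curve.slope
    odds = 2.0**log2_odds
    return odds / (1.0 + odds)


def taqman_imbalance_test(ip: list[float], input_: list[float]) -> TestResult:
    """Paired t-test on log2 VIC/FAM ratios, IP chromatin vs input chromatin."""
    if len(ip) != len(input_):
        raise ValueError(f"IP ({len(ip)}) and input ({len(input_)}) lists must pair up")
    if len(ip) < 2:
        raise ValueError("need at least 2 paired measurements")
    a = np.asarray(ip, dtype=float)
    b = np.asarray(input_, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("VIC/FAM ratios must be positive")
    diffs = np.log2(a) - np.log2(b)
    return _t_one_sample(diffs, "paired t on log2 VIC/FAM, IP vs input (two-sided)")


def chip_qpcr_enrichment(records: pd.DataFrame) -> pd.DataFrame:
    """ChIP-qPCR fold enrichment per region, normalized to the negative control.

    ``records`` needs columns (sample, region, channel, ct) with channel in
    {IP, input}; regions are free-form but one must be ``negative_control``.
    Replicate Ct values (same sample/region/channel) are averaged before the
    exponentiation. Returns per (sample, region): fold = 2^-(Ct_IP-Ct_input)
    and enrichment = fold / fold(negative_control).
    """
    required = {"sample", "region", "channel", "ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    mean_ct = records.groupby(["sample", "region", "channel"])["ct"].mean().unstack("channel")
    for ch in ("IP", "input"):
        if ch not in mean_ct.columns:
            raise ValueError(f"missing channel {ch!r} in records")
    missing = mean_ct[mean_ct.isna().any(axis=1)]
    if len(missing):
        raise ValueError(f"missing IP or input Ct for {missing.index.tolist()}")
    folds = 2.0 ** -(mean_ct["IP"] - mean_ct["input"])
    out = []
    for sample_name, grp in folds.groupby(level="sample"):
        regions = grp.droplevel("sample")
        if "negative_control" not in regions.index:
            raise ValueError(f"sample {sample_name!r} lacks a negative_control region")
        neg = regions["negative_control"]
        for region, fold in regions.items():
            out.append(
                {"sample": sample_name, "region": region, "fold": fold, "enrichment": fold / neg}
            )
    return pd.DataFrame(out)


def qpcr_expression_fold(
    ct: pd.DataFrame,
    *,
    gene: str | None = None,
    normalizer: str = "ACTB",
    treated: str = "treated",
    vehicle: str = "vehicle",
    paired: bool = True,
) -> tuple[pd.DataFrame, TestResult]:
    """Expression fold change of a gene between two treatments, ACTB-normalized.

    ``ct`` needs columns (gene, treatment, replicate, ct). Per replicate the
    expression level is 2^-(Ct_gene - Ct_normalizer); the fold change divides
    treated by vehicle. With ``paired=True`` replicates are matched by index;
    otherwise a single fold of geometric means is formed and no test is run.
    Significance comes from the one-sample t-test on log2 per-replicate folds.
    """
    required = {"gene", "treatment", "replicate", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    genes = set(ct["gene"])
    if normalizer not in genes:
        raise ValueError(f"normalizer gene {normalizer!r} absent from table")
    targets = sorted(genes - {normalizer})
    if gene is None:
        if len(targets) != 1:
            raise ValueError(f"specify gene= (table has targets {targets})")
        gene = targets[0]
    elif gene not in genes:
        raise ValueError(f"gene {gene!r} absent from table")

    wide = ct.pivot_table(index=["treatment", "replicate"], columns="gene", values="ct")
    if wide[[gene, normalizer]].isna().any().any():
        raise ValueError(f"missing {gene} or {normalizer} Ct for some treatment/replicate")
    expr = 2.0 ** -(wide[gene] - wide[normalizer])
    for t in (treated, vehicle):
        if t not in expr.index.get_level_values("treatment"):
            raise ValueError(f"treatment {t!r} absent from table")
    e_t = expr.loc[treated].sort_index()
    e_v = expr.loc[vehicle].sort_index()
    if len(e_t) < 2 or len(e_v) < 2:
        raise ValueError("need at least 2 replicates per treatment")
    if paired:
        if len(e_t) != len(e_v):
            raise ValueError("paired fold change needs equal replicate counts")
        folds = (e_t.to_numpy() / e_v.to_numpy()).tolist()
        table = pd.DataFrame(
            {"replicate": e_t.index, "expr_treated": e_t.to_numpy(), "expr_vehicle": e_v.to_numpy(), "fold": folds}
        )
        result = _t_one_sample(np.log2(np.asarray(folds)), "one-sample t on log2 fold change (two-sided)",
                               estimate=float(np.exp2(np.mean(np.log2(folds)))))
    else:
        fold = float(np.exp2(np.mean(np.log2(e_t))) / np.exp2(np.mean(np.log2(e_v))))
        table = pd.DataFrame({"replicate": ["pooled"], "fold": [fold]})
        result = TestResult("fold of geometric means (no test)", math.nan, math.nan, fold)
    return table, result
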