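"""Hardy-Weinberg equilibrium chi-square test on genotype counts.

Deviation from HWE in *control* genotypes flags possible genotyping error or
population stratification; studies failing the test (p < 0.05 by default)
are kept but marked so the pipeline can run sensitivity analyses with and
without them.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["HweResult", "hwe_chisq", "HWE_ALPHA"]

#: Significance threshold below which a sample is flagged as violating HWE.
HWE_ALPHA = 0.05


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p: float
    risk_allele_freq: float
    in_hwe_at_005: bool
    monomorphic: bool = False


def hwe_chisq(
    genotype_counts: tuple[int, int, int], yates: bool = False
) -> HweResult:
    """Pearson chi-square goodness-of-fit test against HWE proportions.

    For counts (n_RR, n_RN, n_NN), the risk-allele frequency estimate is
    p = (2 n_RR + n_RN) / (2n); expected counts are (n p^2, 2n p(1-p),
    n (1-p)^2) and the statistic has 1 df for a biallelic locus.  A
    monomorphic sample (p in {0, 1}) is returned degenerate with chi2 = 0
    and p = 1.  ``yates`` subtracts the 0.5 continuity correction from each
    absolute deviation; the default is the plain chi-square test.
    """
    n_rr, n_rn, n_nn = genotype_counts
    if min(n_rr, n_rn, n_nn) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_rr + n_rn + n_nn
    if n == 0:
        raise ValueError("empty group: total genotype count is zero")
    p_hat = (2 * n_rr + n_rn) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HweResult(
            chi2=0.0,
            df=1,
            p=1.0,
            risk_allele_freq=p_hat,
            in_hwe_at_005=True,
            monomorphic=True,
        )
    expected = (n * p_hat**2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2)
    chi2 = 0.0
    for obs, exp in zip((n_rr, n_rn, n_nn), expected):
        dev = abs(obs - exp)
        if yates:
            dev = max(0.0, dev - 0.5)
        chi2 += dev * dev / exp
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(
        chi2=float(chi2),
        df=1,
        p=p_value,
        risk_allele_freq=p_hat,
        in_hwe_at_005=p_value >= HWE_ALPHA,
    )
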