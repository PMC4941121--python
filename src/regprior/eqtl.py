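"""Linear-model cis-eQTL association and conditional residual regression.

Genotypes are allele-dosage vectors in {0, 1, 2}; expression is on a
normalized log2 scale.  The marginal association is ordinary least squares
of expression on dosage with a t-test on the slope.  The conditional
association P(SNP1 | SNP2) residualizes expression on SNP2 and tests SNP1
against those residuals; with a single conditioning predictor the t-test
p-value is the same whichever of the two quantities is residualized, so
the expression-residualization form is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Cohort",
    "EqtlResult",
    "eqtl_linear",
    "conditional_eqtl",
    "scan_cis",
    "plot_association",
]

#: default cis window centered on the candidate SNP, bp
CIS_WINDOW_BP = 2_000_000
#: default maximum reported association p-value
MAX_REPORTED_P = 0.05


@dataclass
class Cohort:
    """Genotype dosages and expression for one sample panel.

    ``genotypes``: DataFrame samples x SNPs with entries in {0, 1, 2};
    ``expression``: DataFrame samples x genes of log2-scale values;
    ``covariates``: optional samples x covariates DataFrame.
    """

    genotypes: pd.DataFrame
    expression: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        if len(self.genotypes) != len(self.expression):
            raise ValueError("genotype and expression sample counts differ")
        vals = self.genotypes.to_numpy()
        if not np.isin(vals, (0, 1, 2)).all():
            raise ValueError("genotype dosages must lie in {0, 1, 2}")
        if (self.covariates is not None
                and len(self.covariates) != len(self.genotypes)):
            raise ValueError("covariate sample count differs")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)


@dataclass(frozen=True)
class EqtlResult:
    beta: float
    se: float
    p_value: float
    n: int
    df: int
    collinear: bool = False

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.t.ppf(0.5 + level / 2, self.df) * self.se
        return self.beta - half, self.beta + half


def _ols_slope(x: np.ndarray, y: np.ndarray) -> EqtlResult:
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        p = 0.0 if beta != 0 else 1.0
        t_stat = float("inf") if beta != 0 else 0.0
    else:
        t_stat = beta / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return EqtlResult(beta=beta, se=float(se), p_value=p, n=n, df=df)


def eqtl_linear(genotype, expression) -> EqtlResult:
    """OLS slope of expression on allele dosage, with a t-test p-value."""
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(expression, dtype=float)
    if len(g) != len(y):
        raise ValueError("genotype and expression lengths differ")
    if len(g) < 3:
        raise ValueError("association requires at least 3 samples")
    if np.ptp(g) == 0:
        raise ValueError("monomorphic genotype: no dosage variance")
    return _ols_slope(g, y)


def conditional_eqtl(snp1, snp2, expression) -> EqtlResult:
    """Association of SNP1 with expression residualized on SNP2.

    When SNP1 is perfectly collinear with SNP2 (r^2 = 1) the conditional
    signal is undefined; a flagged null result (beta 0, p 1) is returned.
    """
    g1 = np.asarray(snp1, dtype=float)
    g2 = np.asarray(snp2, dtype=float)
    y = np.asarray(expression, dtype=float)
    if not len(g1) == len(g2) == len(y):
        raise ValueError("input vectors have differing lengths")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise ValueError("monomorphic genotype: no dosage variance")
    r = np.corrcoef(g1, g2)[0, 1]
    if r**2 > 1 - 1e-10:
        return EqtlResult(beta=0.0, se=float("nan"), p_value=1.0,
                          n=len(y), df=len(y) - 3, collinear=True)
    fit2 = _ols_slope(g2, y)
    residuals = (y - y.mean()) - fit2.beta * (g2 - g2.mean())
    return _ols_slope(g1, residuals)


def scan_cis(
    cohort: Cohort,
    snp_positions: dict[str, tuple[str, int]],
    gene_positions: dict[str, tuple[str, int]],
    cis_window_bp: int = CIS_WINDOW_BP,
    max_p: float = MAX_REPORTED_P,
) -> pd.DataFrame:
    """All SNP-gene associations within the cis window, filtered by p-value.

    Positions map identifiers to (chrom, bp); the window is centered on
    each SNP.  Returns a DataFrame (snp, gene, distance_bp, beta, se, p)
    sorted by p, keeping rows with p <= max_p.
    """
    rows = []
    half = cis_window_bp // 2
    for snp in cohort.genotypes.columns:
        if snp not in snp_positions:
            continue
        s_chrom, s_pos = snp_positions[snp]
        g_vec = cohort.genotypes[snp].to_numpy()
        if np.ptp(g_vec) == 0:
            continue
        for gene in cohort.expression.columns:
            if gene not in gene_positions:
                continue
            g_chrom, g_pos = gene_positions[gene]
            if g_chrom != s_chrom or abs(g_pos - s_pos) > half:
                continue
            res = eqtl_linear(g_vec, cohort.expression[gene].to_numpy())
            if res.p_value <= max_p:
                rows.append({
                    "snp": snp, "gene": gene,
                    "distance_bp": int(g_pos - s_pos),
                    "beta": res.beta, "se": res.se, "p": res.p_value,
                })
    return pd.DataFrame(
        rows, columns=["snp", "gene", "distance_bp", "beta", "se", "p"]
    ).sort_values("p", ignore_index=True)


def plot_association(assoc: pd.DataFrame, ax=None):
    """Plain offset vs -log10(p) scatter of a cis association table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.scatter(assoc["distance_bp"] / 1e3, -np.log10(assoc["p"]), s=12)
    ax.set_xlabel("distance from SNP (kb)")
    ax.set_ylabel("-log10 p")
    return ax
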