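"""Strain-level phenotype statistics on the log2 scale.

Summaries (mean +/- SEM of log2 IgE per strain and condition), two-sample
parental contrasts, Dunnett many-to-one comparisons of each recombinant
congenic strain against its major-donor parent (flagging "informative"
strains), and Bonferroni-adjusted three-group comparisons for consomic
strain designs.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("animal_id", "strain", "condition", "ige_ng_ml")


class PhenotypeDataError(ValueError):
    pass


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table and return it with a log2 column attached."""
    missing = [c for c in REQUIRED_COLUMNS if c not in pheno.columns]
    if missing:
        raise PhenotypeDataError(f"phenotype table missing columns: {missing}")
    ige = pd.to_numeric(pheno["ige_ng_ml"], errors="coerce")
    bad = pheno.index[~(ige > 0)]
    if len(bad):
        row = pheno.loc[bad[0]]
        raise PhenotypeDataError(
            f"non-positive or non-numeric IgE for animal "
            f"{row['animal_id']!r} (strain {row['strain']!r}): "
            f"{row['ige_ng_ml']!r}; log2 transform requires IgE > 0"
        )
    out = pheno.copy()
    out["log2_ige"] = np.log2(ige.astype(float))
    return out


def _group_values(pheno: pd.DataFrame, strain: str, condition: str) -> np.ndarray:
    sel = (pheno["strain"] == strain) & (pheno["condition"] == condition)
    vals = pheno.loc[sel, "log2_ige"].to_numpy()
    if vals.size == 0:
        raise KeyError(
            f"no records for strain {strain!r} in condition {condition!r}"
        )
    return vals


def summarize_strains(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per (strain, condition) mean and SEM of log2(IgE).

    Returns columns ``strain, condition, n, mean_log2, sem_log2``. Groups
    with a single animal get SEM = NaN (variance undefined) with a warning.
    """
    pheno = validate_phenotypes(pheno)
    rows = []
    for (strain, cond), grp in pheno.groupby(["strain", "condition"], sort=False):
        vals = grp["log2_ige"].to_numpy()
        n = vals.size
        if n < 2:
            logger.warning(
                "strain %s / condition %s has n=%d; SEM undefined", strain, cond, n
            )
            sem = np.nan
        else:
            sem = float(np.std(vals, ddof=1) / np.sqrt(n))
        rows.append(
            {
                "strain": strain,
                "condition": cond,
                "n": n,
                "mean_log2": float(vals.mean()),
                "sem_log2": sem,
            }
        )
    return pd.DataFrame(rows)


def parental_contrast(
    pheno: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    condition: str,
    equal_var: bool = True,
) -> float:
    """Two-sided two-sample t-test p-value on log2 IgE between two strains.

    Pooled-variance by default (Welch with ``equal_var=False``). Two
    identical constant groups are a null by construction and return p = 1.
    """
    pheno = validate_phenotypes(pheno)
    x = _group_values(pheno, strain_a, condition)
    y = _group_values(pheno, strain_b, condition)
    if x.size < 2 or y.size < 2:
        raise PhenotypeDataError("both groups need n >= 2 for a t-test")
    if np.isclose(x.mean(), y.mean()) and np.std(x) == 0 and np.std(y) == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):  # zero pooled variance with unequal means
        return 0.0
    return p


# --------------------------------------------------------------------------
# Dunnett many-to-one
# --------------------------------------------------------------------------

def _dunnett_max_abs_cdf(
    t: float, lam: np.ndarray, df: int, n_nodes: int = 64
) -> float:
    """P(max_i |T_i| <= t) for the Dunnett null distribution.

    The T_i share a studentising chi factor and have correlation
    rho_ij = lam_i * lam_j (lam_i = sqrt(n_i / (n_i + n_0)) for contrasts
    against a common control). Conditioning on the shared standard normal Z0
    and the chi factor U makes the coordinates independent; the two outer
    integrals are evaluated by Gauss-Hermite (Z0) x Gauss-Legendre on the
    chi probability scale (U).
    """
    if t <= 0:
        return 0.0
    lam = np.asarray(lam, dtype=float)
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_nodes)  # weight e^{-z^2/2}
    gh_w = gh_w / np.sqrt(2 * np.pi)
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_nodes)
    pgrid = 0.5 * (gl_x + 1.0)  # nodes on (0,1)
    gl_w = 0.5 * gl_w
    u = stats.chi.ppf(pgrid, df) / np.sqrt(df)

    z = gh_x[:, None, None]          # (nodes, 1, 1)
    uu = u[None, :, None]            # (1, nodes, 1)
    l = lam[None, None, :]           # (1, 1, k)
    s = np.sqrt(1.0 - l ** 2)
    upper = (t * uu - l * z) / s
    lower = (-t * uu - l * z) / s
    probs = special.ndtr(upper) - special.ndtr(lower)
    inner = probs.prod(axis=2)       # (nodes, nodes)
    return float(gh_w @ inner @ gl_w)


def _dunnett_adjusted_p(
    t_obs: np.ndarray,
    lam: np.ndarray,
    df: int,
    method: str = "quadrature",
    n_mc: int = 100_000,
    seed: int | None = 0,
) -> np.ndarray:
    """Two-sided familywise-adjusted p-values P(max_j |T_j| >= |t_i|)."""
    t_obs = np.abs(np.asarray(t_obs, dtype=float))
    if method == "quadrature":
        return np.array(
            [1.0 - _dunnett_max_abs_cdf(t, lam, df) for t in t_obs]
        )
    if method == "mc":
        rng = np.random.default_rng(seed)
        z0 = rng.standard_normal(n_mc)
        zi = rng.standard_normal((n_mc, lam.size))
        u = np.sqrt(rng.chisquare(df, n_mc) / df)
        tnull = (lam * z0[:, None] + np.sqrt(1 - lam ** 2) * zi) / u[:, None]
        mx = np.abs(tnull).max(axis=1)
        return np.array([(mx >= t).mean() for t in t_obs])
    raise ValueError(f"unknown Dunnett method: {method!r}")


def dunnett_many_to_one(
    pheno: pd.DataFrame,
    reference_strain: str,
    test_strains: list[str],
    condition: str,
    alpha: float = 0.05,
    balanced_correlation: bool = False,
    method: str = "quadrature",
    n_mc: int = 100_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Dunnett comparison of each test strain against a common reference.

    t statistics use the error variance pooled across all groups (the
    one-way ANOVA mean squared error); adjusted p-values come from the
    equicorrelated multivariate-t null of the max |T| statistic, with the
    correlation structure implied by the pairwise group sizes (or the
    balanced rho = 1/2 structure when ``balanced_correlation`` is set).

    Returns one row per test strain: ``strain, condition, n, raw_p,
    adjusted_p, significant, direction``.
    """
    if len(test_strains) == 0:
        return pd.DataFrame(
            columns=[
                "strain", "condition", "n", "raw_p",
                "adjusted_p", "significant", "direction",
            ]
        )
    pheno = validate_phenotypes(pheno)
    ref = _group_values(pheno, reference_strain, condition)
    groups = [_group_values(pheno, s, condition) for s in test_strains]
    sizes = np.array([g.size for g in groups])
    if ref.size < 2 or (sizes < 2).any():
        raise PhenotypeDataError("all groups need n >= 2 for Dunnett comparisons")

    all_groups = [ref] + groups
    n_total = sum(g.size for g in all_groups)
    df = n_total - len(all_groups)
    ss = sum(((g - g.mean()) ** 2).sum() for g in all_groups)
    s2 = ss / df
    if s2 == 0:
        logger.warning("pooled variance is zero; comparisons are degenerate")
        return pd.DataFrame(
            {
                "strain": test_strains,
                "condition": condition,
                "n": sizes,
                "raw_p": np.nan,
                "adjusted_p": np.nan,
                "significant": False,
                "direction": [
                    int(np.sign(g.mean() - ref.mean())) for g in groups
                ],
            }
        )

    diffs = np.array([g.mean() - ref.mean() for g in groups])
    se = np.sqrt(s2 * (1.0 / sizes + 1.0 / ref.size))
    t_stats = diffs / se
    raw_p = 2.0 * stats.t.sf(np.abs(t_stats), df)

    if balanced_correlation:
        lam = np.full(len(groups), np.sqrt(0.5))
    else:
        lam = np.sqrt(sizes / (sizes + ref.size))
    adj_p = _dunnett_adjusted_p(t_stats, lam, df, method=method, n_mc=n_mc, seed=seed)
    adj_p = np.minimum(1.0, np.maximum(adj_p, raw_p))

    return pd.DataFrame(
        {
            "strain": test_strains,
            "condition": condition,
            "n": sizes,
            "raw_p": raw_p,
            "adjusted_p": adj_p,
            "significant": adj_p <= alpha,
            "direction": np.sign(diffs).astype(int),
        }
    )


def bonferroni_three_group(
    pheno: pd.DataFrame, strains: list[str], condition: str
) -> pd.DataFrame:
    """All three pairwise contrasts among exactly three strains on the pooled
    one-way ANOVA error, Bonferroni-adjusted (p x 3, capped at 1)."""
    if len(strains) != 3:
        raise ValueError("bonferroni_three_group requires exactly three strains")
    pheno = validate_phenotypes(pheno)
    groups = {s: _group_values(pheno, s, condition) for s in strains}
    n_total = sum(g.size for g in groups.values())
    df = n_total - 3
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    s2 = ss / df

    rows = []
    pairs = [(0, 1), (0, 2), (1, 2)]
    for i, j in pairs:
        a, b = strains[i], strains[j]
        ga, gb = groups[a], groups[b]
        if s2 == 0:
            raw = 1.0 if ga.mean() == gb.mean() else 0.0
        else:
            t = (ga.mean() - gb.mean()) / np.sqrt(s2 * (1 / ga.size + 1 / gb.size))
            raw = float(2.0 * stats.t.sf(abs(t), df))
        rows.append(
            {
                "strain_1": a,
                "strain_2": b,
                "condition": condition,
                "raw_p": raw,
                "adjusted_p": min(1.0, 3.0 * raw),
                "direction": int(np.sign(ga.mean() - gb.mean())),
            }
        )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """GraphPad-style asterisk coding: *** <0.001, ** <0.01, * <0.05."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
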