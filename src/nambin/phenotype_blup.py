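"""Cross-environment BLUPs and broad-sense heritability.

Model: trait value y_ier = mu + env_e (fixed) + line_i (random) +
(line x env)_ie + error.  Variance components come from the classical
method-of-moments equations on the line, line-by-environment and residual
mean squares (negative estimates truncated at zero); exact REML is not
needed for balanced or mildly unbalanced RIL trials and the closed forms
keep every quantity auditable.

Broad-sense heritability on a line-mean basis:

    H^2 = sigma2_g / (sigma2_g + sigma2_ge / E + sigma2_e / (E R))

Line BLUPs shrink environment-adjusted line means toward the grand mean by
sigma2_g / (sigma2_g + sigma2_ge / E_i + sigma2_e / n_i), with per-line
effective replication handling unbalanced data.  The general mixed-model
(Henderson) solver in :func:`blup_lines_mme` is the cross-check for the
closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class VarianceComponents:
    var_g: float        # line (genotypic)
    var_ge: float       # line x environment
    var_e: float        # residual
    n_env: int
    n_rep: float        # average replicates per line x env cell

    def __post_init__(self):
        for name in ("var_g", "var_ge", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")


def estimate_components(table):
    """Method-of-moments ANOVA components from a PhenotypeTable.

    With a single unreplicated environment the line-by-environment and
    residual variances are confounded; the confounded residual is returned in
    ``var_e`` with a warning.
    """
    df = table.df
    lines = df["line"].unique()
    envs = df["env"].unique()
    if len(lines) < 2 or len(envs) < 1:
        raise ValueError("need at least two lines and one environment")
    n_env = len(envs)
    cell = df.groupby(["line", "env"])["value"].agg(["mean", "count", "var"])
    r_bar = float(cell["count"].mean())
    grand = df["value"].mean()
    line_means = df.groupby("line")["value"].mean()
    env_means = df.groupby("env")["value"].mean()
    # residual (within line x env cell)
    if r_bar > 1.0:
        ss_err = float(((cell["var"] * (cell["count"] - 1)).fillna(0)).sum())
        df_err = int((cell["count"] - 1).sum())
        ms_err = ss_err / df_err if df_err > 0 else 0.0
    else:
        ms_err = None
    if n_env < 2:
        warnings.warn("single environment: line x env and residual variances "
                      "are confounded", stacklevel=2)
        resid = df["value"] - df["line"].map(line_means)
        var_conf = float((resid ** 2).sum() / max(len(df) - len(lines), 1))
        var_g = max(0.0, float(line_means.var(ddof=1)) - var_conf / max(r_bar, 1.0))
        return VarianceComponents(var_g=var_g, var_ge=0.0, var_e=var_conf,
                                  n_env=1, n_rep=r_bar)
    # mean squares on cell means (balanced-theory expectations)
    wide = cell["mean"].unstack()
    ms_line = float(wide.mean(axis=1).var(ddof=1)) * n_env
    inter = wide.sub(wide.mean(axis=1), axis=0).sub(wide.mean(axis=0), axis=1) + wide.values.mean()
    ss_inter = float((inter ** 2).sum().sum())
    ms_inter = ss_inter / ((len(lines) - 1) * (n_env - 1))
    if ms_err is None:
        # unreplicated multi-environment: interaction is the residual
        var_ge = 0.0
        var_e = ms_inter
        var_g = max(0.0, (ms_line - ms_inter) / n_env)
        warnings.warn("unreplicated trials: line x env and residual variances "
                      "are confounded; reporting their sum as var_e", stacklevel=2)
        return VarianceComponents(var_g=var_g, var_ge=var_ge, var_e=var_e,
                                  n_env=n_env, n_rep=r_bar)
    # here MS are on cell means, so E[ms_inter] = var_ge + var_e / r
    var_ge = max(0.0, ms_inter - ms_err / r_bar)
    var_g = max(0.0, (ms_line - ms_inter) / n_env)
    return VarianceComponents(var_g=var_g, var_ge=var_ge, var_e=ms_err,
                              n_env=n_env, n_rep=r_bar)


def h2_mean_basis(comp):
    """Broad-sense heritability on a line-mean basis."""
    denom = comp.var_g + comp.var_ge / comp.n_env + comp.var_e / (comp.n_env * comp.n_rep)
    if denom == 0:
        raise ValueError("all variance components are zero; H2 undefined")
    return comp.var_g / denom


def blup_lines(table, comp=None):
    """Per-line BLUPs of the cross-environment genotypic value.

    Environment effects are fixed (estimated as environment means of the
    env-centered data); line effects are random and shrunk by
    var_g / (var_g + var_ge/E_i + var_e/n_i) with E_i environments and n_i
    plots observed for line i.  Returns a Series indexed by line, on the
    trait scale (grand mean added back).  Lines with no observations are
    absent from the result.
    """
    comp = comp or estimate_components(table)
    df = table.df.copy()
    grand = df["value"].mean()
    env_eff = df.groupby("env")["value"].mean() - grand
    df["adj"] = df["value"] - df["env"].map(env_eff)
    per_line = df.groupby("line").agg(
        adj_mean=("adj", "mean"), n=("adj", "size"), n_env=("env", "nunique"))
    resid_var = comp.var_ge / per_line["n_env"] + comp.var_e / per_line["n"]
    if comp.var_g == 0.0:
        shrink = pd.Series(0.0, index=per_line.index)
    else:
        shrink = comp.var_g / (comp.var_g + resid_var)
    blup = grand + shrink * (per_line["adj_mean"] - grand)
    blup.name = "blup"
    return blup


def blup_lines_mme(table, comp=None):
    """Henderson mixed-model-equation solver (general cross-check).

    y = X b + Z u + e with fixed environments and random lines,
    u ~ N(0, var_u I), e ~ N(0, var_r I), where var_u = var_g and the
    residual pools var_ge and var_e at plot level.  Returns line BLUPs on
    the trait scale.
    """
    comp = comp or estimate_components(table)
    df = table.df
    lines = sorted(df["line"].unique())
    envs = sorted(df["env"].unique())
    n = len(df)
    X = np.zeros((n, len(envs)))
    X[np.arange(n), [envs.index(e) for e in df["env"]]] = 1.0
    Z = np.zeros((n, len(lines)))
    Z[np.arange(n), [lines.index(l) for l in df["line"]]] = 1.0
    y = df["value"].to_numpy(dtype=float)
    var_u = comp.var_g
    var_r = comp.var_ge + comp.var_e
    if var_u == 0.0:
        return pd.Series(float(y.mean()), index=pd.Index(lines, name="line"), name="blup")
    lam = var_r / var_u
    top = np.hstack([X.T @ X, X.T @ Z])
    bot = np.hstack([Z.T @ X, Z.T @ Z + lam * np.eye(len(lines))])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    u = sol[len(envs):]
    beta = sol[:len(envs)]
    return pd.Series(float(np.mean(beta)) + u, index=pd.Index(lines, name="line"),
                     name="blup")
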