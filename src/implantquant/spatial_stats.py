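"""Mixed-effects distance-trend analysis of band fraction profiles.

The spatial readout of the band quantification is, for every image, the
fraction of positive pixels as a function of band depth from the implant
edge. To compare infiltration gradients between treatment groups over time,
these profiles are fit with a linear mixed model:

    fraction ~ group * timepoint * distance   (all interactions, fixed)
    + random intercept per mouse
    + random intercept per image replicate (nested in mouse)

fit by restricted maximum likelihood. The quantity of interest is the
marginal slope with respect to distance in each group x timepoint cell
(fraction per um), with pairwise slope contrasts between cells under a
Tukey (default), Holm or unadjusted multiplicity correction.

Fractions are modeled on the identity scale by default; a logit transform
is available for responses near the boundary. Confidence intervals use a
t reference with residual degrees of freedom (n - p); the output records
which reference was used.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TrendModelSpec:
    """Specification of the distance-trend model."""

    response: str = "fraction_positive"
    distance: str = "mid_depth_um"
    group: str = "group"
    timepoint: str = "timepoint"
    mouse: str = "mouse_id"
    replicate: str = "image_id"  # image replicate identifier (nested in mouse)
    include_random: bool = True
    logit: bool = False

    def formula(self, data: pd.DataFrame) -> str:
        terms = []
        if data[self.group].nunique() > 1:
            terms.append(f"C({self.group})")
        if data[self.timepoint].nunique() > 1:
            terms.append(f"C({self.timepoint})")
        terms.append(self.distance)
        rhs = " * ".join(terms)
        return f"__response__ ~ {rhs}"


@dataclass
class FittedTrendModel:
    """A fitted distance-trend model plus everything contrasts need."""

    result: object
    spec: TrendModelSpec
    data: pd.DataFrame
    design_info: object
    converged: bool
    singular: bool
    df_resid: float

    @property
    def fe_params(self) -> pd.Series:
        fe = getattr(self.result, "fe_params", None)
        return fe if fe is not None else self.result.params

    def fe_cov(self) -> np.ndarray:
        k = len(self.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]

    def summary_dict(self) -> dict:
        return {
            "formula": self.spec.formula(self.data),
            "n_obs": int(len(self.data)),
            "converged": bool(self.converged),
            "singular": bool(self.singular),
            "random_effects": bool(self.spec.include_random),
            "df_resid": float(self.df_resid),
            "fe_params": {k: float(v) for k, v in self.fe_params.items()},
        }


def _prepare(records: pd.DataFrame, spec: TrendModelSpec) -> pd.DataFrame:
    df = records.copy()
    required = [spec.response, spec.distance, spec.group, spec.timepoint, spec.mouse]
    if spec.include_random:
        required.append(spec.replicate)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"records lack required column {col!r}")
    if df.groupby([spec.group, spec.timepoint])[spec.distance].nunique().min() < 2:
        raise ValueError(
            "need at least two distance values per group x timepoint cell"
        )
    y = df[spec.response].to_numpy(dtype=float)
    if spec.logit:
        eps = 1e-6
        y = np.log(np.clip(y, eps, 1 - eps) / (1 - np.clip(y, eps, 1 - eps)))
    df["__response__"] = y
    return df


def fit_distance_trend(
    records: pd.DataFrame, spec: TrendModelSpec | None = None
) -> FittedTrendModel:
    """Fit the distance-trend mixed model to band fraction records by REML.

    With ``spec.include_random=False`` the same fixed-effects structure is
    fit by ordinary least squares (the limiting model when mouse and
    replicate variances are zero). A rank-deficient fixed-effects design
    raises an error naming the aliased columns; a singular random-effects
    fit is reported via ``singular=True`` with a warning, not an error.
    """
    spec = spec or TrendModelSpec()
    df = _prepare(records, spec)
    formula = spec.formula(df)
    y_dm, x_dm = patsy.dmatrices(formula, df, return_type="dataframe")
    X = np.asarray(x_dm)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns not supporting the rank via pivoted QR
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(X, pivoting=True, mode="economic")
        aliased = [x_dm.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient fixed-effects design; aliased: {aliased}")
    singular = False
    if spec.include_random:
        vc = {"replicate": f"0 + C({spec.replicate})"}
        model = smf.mixedlm(
            formula, df, groups=df[spec.mouse], re_formula="1", vc_formula=vc
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = model.fit(reml=True)
        for wmsg in caught:
            if "singular" in str(wmsg.message).lower() or "boundary" in str(
                wmsg.message
            ).lower():
                singular = True
        if singular:
            warnings.warn(
                "random-effects covariance is singular (a variance component "
                f"is at zero): {result.cov_re.to_dict()}",
                stacklevel=2,
            )
        converged = bool(getattr(result, "converged", True))
    else:
        result = smf.ols(formula, df).fit()
        converged = True
    df_resid = float(len(df) - X.shape[1])
    return FittedTrendModel(
        result=result,
        spec=spec,
        data=df,
        design_info=x_dm.design_info,
        converged=converged,
        singular=singular,
        df_resid=df_resid,
    )


@dataclass
class SlopeEstimates:
    """Marginal distance slopes per group x timepoint cell."""

    frame: pd.DataFrame  # group, timepoint, slope, se, ci_low, ci_high, df
    cov: np.ndarray  # covariance of the slope estimates
    df: float
    df_method: str = "residual"

    def __len__(self) -> int:
        return len(self.frame)


def marginal_slopes(model: FittedTrendModel, conf_level: float = 0.95) -> SlopeEstimates:
    """Marginal linear trends in distance for every group x timepoint cell.

    Each slope is a contrast of the fixed effects: the difference of the
    design row at distance d+1 and at distance d for that cell, so it equals
    the distance coefficient plus the cell's interaction terms. Standard
    errors come from the fitted fixed-effects covariance; intervals use a t
    reference on residual degrees of freedom.
    """
    spec = model.spec
    data = model.data
    cells = (
        data[[spec.group, spec.timepoint]]
        .drop_duplicates()
        .sort_values([spec.group, spec.timepoint])
        .reset_index(drop=True)
    )
    L = np.zeros((len(cells), len(model.fe_params)))
    for i, row in cells.iterrows():
        base = {
            spec.group: [row[spec.group]],
            spec.timepoint: [row[spec.timepoint]],
            spec.distance: [0.0],
        }
        hi = dict(base, **{spec.distance: [1.0]})
        (x0,) = patsy.build_design_matrices([model.design_info], pd.DataFrame(base))
        (x1,) = patsy.build_design_matrices([model.design_info], pd.DataFrame(hi))
        L[i] = np.asarray(x1)[0] - np.asarray(x0)[0]
    beta = np.asarray(model.fe_params)
    cov_fe = model.fe_cov()
    slopes = L @ beta
    cov = L @ cov_fe @ L.T
    se = np.sqrt(np.diag(cov))
    if (se <= 0).any():
        raise RuntimeError("non-positive slope standard error; fit is degenerate")
    tcrit = stats.t.ppf(0.5 + conf_level / 2, model.df_resid)
    frame = pd.DataFrame(
        {
            "group": cells[spec.group],
            "timepoint": cells[spec.timepoint],
            "slope": slopes,
            "se": se,
            "ci_low": slopes - tcrit * se,
            "ci_high": slopes + tcrit * se,
            "df": model.df_resid,
        }
    )
    return SlopeEstimates(frame, cov, model.df_resid)


def slope_contrasts(slopes: SlopeEstimates, adjust: str = "tukey") -> pd.DataFrame:
    """All pairwise differences between cell slopes with multiplicity control.

    ``tukey`` uses the studentized-range reference over the k cells (the
    family used for post-hoc cell comparisons); ``holm`` applies step-down
    Bonferroni to the raw t p-values; ``none`` reports raw p-values.
    Adjusted p-values are never smaller than raw ones.
    """
    if adjust not in ("tukey", "holm", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    k = len(slopes)
    if k < 2:
        raise ValueError("need at least two cells to contrast")
    est = slopes.frame["slope"].to_numpy()
    labels = [
        f"{g}:{t}" for g, t in zip(slopes.frame["group"], slopes.frame["timepoint"])
    ]
    rows = []
    raw_ps = []
    for i, j in itertools.combinations(range(k), 2):
        diff = est[i] - est[j]
        var = slopes.cov[i, i] + slopes.cov[j, j] - 2 * slopes.cov[i, j]
        se = float(np.sqrt(max(var, 0.0)))
        tval = diff / se if se > 0 else 0.0
        p_raw = 2 * stats.t.sf(abs(tval), slopes.df) if se > 0 else 1.0
        rows.append(
            {"cell_a": labels[i], "cell_b": labels[j], "difference": diff,
             "se": se, "t": tval, "p_raw": p_raw}
        )
        raw_ps.append(p_raw)
    out = pd.DataFrame(rows)
    if adjust == "none" or k == 2:
        out["p_adj"] = out["p_raw"]
    elif adjust == "holm":
        out["p_adj"] = multipletests(raw_ps, method="holm")[1]
    else:  # tukey: studentized range with k means
        q = np.abs(out["t"].to_numpy()) * np.sqrt(2.0)
        out["p_adj"] = stats.studentized_range.sf(q, k, slopes.df)
    out["p_adj"] = np.minimum(1.0, np.maximum(out["p_adj"], out["p_raw"]))
    out["adjust"] = adjust
    return out


def plot_trends(
    model: FittedTrendModel,
    slopes: SlopeEstimates,
    path: str | None = None,
    conf_level: float = 0.95,
):
    """Plot observed band fractions and fitted lines with CI ribbons, one
    panel per group (mirrors the usual presentation of distance profiles)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = model.spec
    data = model.data
    groups = sorted(data[spec.group].unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 4),
                             squeeze=False, sharey=True)
    tcrit = stats.t.ppf(0.5 + conf_level / 2, model.df_resid)
    beta = np.asarray(model.fe_params)
    cov_fe = model.fe_cov()
    for ax, g in zip(axes[0], groups):
        sub = data[data[spec.group] == g]
        for t in sorted(sub[spec.timepoint].unique()):
            cell = sub[sub[spec.timepoint] == t]
            ax.scatter(cell[spec.distance], cell[spec.response], s=8, alpha=0.4)
            xs = np.linspace(cell[spec.distance].min(), cell[spec.distance].max(), 50)
            grid = pd.DataFrame(
                {spec.group: g, spec.timepoint: t, spec.distance: xs}
            )
            (X,) = patsy.build_design_matrices([model.design_info], grid)
            X = np.asarray(X)
            yhat = X @ beta
            se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov_fe, X))
            ax.plot(xs, yhat, label=f"month {t}")
            ax.fill_between(xs, yhat - tcrit * se, yhat + tcrit * se,
                            alpha=0.2, color="grey")
        ax.set_title(str(g))
        ax.set_xlabel("depth from implant edge (um)")
        ax.legend(fontsize=8)
    axes[0][0].set_ylabel(spec.response)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
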