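"""Redundancy analysis (RDA) linking pool allele frequencies to environmental
predictors.

RDA is a constrained ordination: the multivariate response Y (pools x SNPs,
column-centered allele frequencies) is regressed on the predictor matrix X
(pools x standardized environmental variables) by ordinary least squares, and
the fitted values Y_hat = X (X'X)^-1 X' Y are eigen-decomposed. The
constrained axes span the environment-associated part of the genetic
variance; the proportion constrained is tr(Y_hat'Y_hat) / tr(Y'Y).
Significance of the model, each axis, and each predictor is assessed with
permutation pseudo-F tests; candidate SNPs are those with extreme loadings on
significantly constrained axes.

The module follows a model/results layout: build :class:`RDA` from the two
matrices, call :meth:`RDA.fit`, and query the returned :class:`RDAResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError

# ---------------------------------------------------------------------------
# environment preparation


def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Standardize every numeric column to zero mean and unit (ddof=1)
    variance; a non-numeric ``site_id`` column is passed through unchanged."""
    out = env.copy()
    cols = [c for c in env.columns if c != "site_id"]
    if len(env) < 2:
        raise ValidationError("need >= 2 sites to standardize")
    for c in cols:
        x = env[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"constant environmental column {c!r}")
        out[c] = (x - x.mean()) / sd
    return out


def prune_correlated(
    env: pd.DataFrame, r2_threshold: float = 0.7, priority: list[str] | None = None
) -> list[str]:
    """Greedy removal of collinear predictors: walk the variables in priority
    order and keep one iff its squared Pearson correlation with every
    already-kept variable is below the threshold."""
    cols = [c for c in env.columns if c != "site_id"]
    if priority:
        order = [c for c in priority if c in cols] + [c for c in cols if c not in priority]
    else:
        order = cols
    kept: list[str] = []
    for c in order:
        x = env[c].to_numpy(dtype=float)
        ok = True
        for k in kept:
            r = np.corrcoef(x, env[k].to_numpy(dtype=float))[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# the model


class RDA:
    """Redundancy analysis of ``response`` (samples x features) on
    ``predictors`` (samples x variables).

    Both frames must share the same index (pool/site ids). Response columns
    are centered internally; predictors are used as given (standardize first
    with :func:`standardize_env`).
    """

    def __init__(self, response: pd.DataFrame, predictors: pd.DataFrame):
        if list(response.index) != list(predictors.index):
            raise ValidationError("response and predictor rows must align")
        self.response = response.astype(float)
        self.predictors = predictors.astype(float)
        n, p = predictors.shape
        if p > n - 2:
            raise ValidationError(f"{p} predictors with only {n} samples (need p <= n - 2)")
        X = self.predictors.to_numpy()
        Xc = X - X.mean(axis=0, keepdims=True)
        if np.linalg.matrix_rank(Xc) < p:
            raise ValidationError("rank-deficient predictor matrix")

    def fit(self) -> "RDAResults":
        Y = self.response.to_numpy()
        Yc = Y - Y.mean(axis=0, keepdims=True)
        X = self.predictors.to_numpy()
        Xc = X - X.mean(axis=0, keepdims=True)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ beta
        U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
        keep = s**2 > 1e-12 * max((s**2).sum(), 1e-30)
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
        total_var = float((Yc**2).sum())
        constrained_var = float((s**2).sum())
        return RDAResults(
            model=self,
            Yc=Yc,
            Xc=Xc,
            site_scores=U * s,
            singular_values=s,
            snp_loadings=Vt.T,
            total_var=total_var,
            constrained_var=constrained_var,
        )


@dataclass
class CandidateSnp:
    snp: str
    axis: int  # 1-based
    loading: float
    best_predictor: str
    r2: float


class RDAResults:
    """Fitted RDA: axis scores, variances, loadings, permutation tests and
    candidate-SNP extraction."""

    def __init__(self, model, Yc, Xc, site_scores, singular_values, snp_loadings,
                 total_var, constrained_var):
        self.model = model
        self._Yc = Yc
        self._Xc = Xc
        self.site_scores = pd.DataFrame(
            site_scores,
            index=model.response.index,
            columns=[f"RDA{i + 1}" for i in range(site_scores.shape[1])],
        )
        self.singular_values = singular_values
        self.eigenvalues = singular_values**2
        self.snp_loadings = pd.DataFrame(
            snp_loadings,
            index=model.response.columns,
            columns=self.site_scores.columns,
        )
        self.total_var = total_var
        self.constrained_var = constrained_var

    @property
    def proportion_constrained(self) -> float:
        if self.total_var == 0:
            return 0.0
        return self.constrained_var / self.total_var

    @property
    def axis_pct_of_constrained(self) -> np.ndarray:
        if self.constrained_var == 0:
            return np.zeros(0)
        return 100.0 * self.eigenvalues / self.constrained_var

    def predictor_loadings(self) -> pd.DataFrame:
        """Biplot arrows: correlations of each predictor with the axis scores."""
        out = {}
        for c in self.model.predictors.columns:
            x = self.model.predictors[c].to_numpy()
            out[c] = [
                np.corrcoef(x, self.site_scores[a])[0, 1] for a in self.site_scores.columns
            ]
        return pd.DataFrame(out, index=self.site_scores.columns).T

    # -- permutation inference ---------------------------------------------

    def _pseudo_f(self, Yc: np.ndarray, Xc: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ beta
        ss_fit = (fitted**2).sum()
        ss_res = ((Yc - fitted) ** 2).sum()
        n, p = Xc.shape
        df2 = n - p - 1
        if ss_res <= 0 or df2 <= 0:
            return np.inf
        return (ss_fit / p) / (ss_res / df2)

    def permutation_test(self, n_perm: int = 1000, seed: int = 0) -> dict:
        """Permutation significance of the whole model, each axis
        (sequentially, stopping at the first non-significant axis) and each
        predictor (marginal, permuting that predictor's residuals given the
        others).

        Returns a dict with keys ``model`` (float p), ``axes`` (list of p,
        NaN beyond the stopping point) and ``predictors`` (Series of p).
        """
        import warnings

        if n_perm < 19:
            raise ValidationError("n_perm < 19 cannot resolve alpha = 0.05")
        if n_perm < 99:
            warnings.warn("n_perm < 99 gives coarse p-values", stacklevel=2)
        rng = np.random.default_rng(seed)
        Yc, Xc = self._Yc, self._Xc
        n, p = Xc.shape
        df2 = n - p - 1

        f_obs = self._pseudo_f(Yc, Xc)
        perms = [rng.permutation(n) for _ in range(n_perm)]
        n_ge = sum(1 for pr in perms if self._pseudo_f(Yc, Xc[pr]) >= f_obs)
        p_model = (1 + n_ge) / (n_perm + 1)

        # axis tests: pseudo-F of each eigenvalue against the residual variance
        ss_res = max(self.total_var - self.constrained_var, 0.0)
        axes_p = []
        k_axes = self.eigenvalues.size
        f_axis_obs = [
            np.inf if ss_res <= 0 else (ev / 1.0) / (ss_res / df2) for ev in self.eigenvalues
        ]
        perm_eigs = []
        for pr in perms:
            beta, *_ = np.linalg.lstsq(Xc[pr], Yc, rcond=None)
            fitted = Xc[pr] @ beta
            sv = np.linalg.svd(fitted, compute_uv=False)
            ssr = ((Yc - fitted) ** 2).sum()
            perm_eigs.append((sv**2, ssr))
        stopped = False
        for k in range(k_axes):
            if stopped:
                axes_p.append(float("nan"))
                continue
            n_ge = 0
            for sv2, ssr in perm_eigs:
                ev = sv2[k] if k < sv2.size else 0.0
                f_perm = np.inf if ssr <= 0 else ev / (ssr / df2)
                if f_perm >= f_axis_obs[k]:
                    n_ge += 1
            pk = (1 + n_ge) / (n_perm + 1)
            axes_p.append(pk)
            if pk > 0.05:
                stopped = True

        # marginal predictor tests
        pred_p = {}
        cols = list(self.model.predictors.columns)
        for j, name in enumerate(cols):
            others = np.delete(Xc, j, axis=1)
            xj = Xc[:, j]
            if others.shape[1]:
                g, *_ = np.linalg.lstsq(others, xj, rcond=None)
                xfit = others @ g
            else:
                xfit = np.zeros_like(xj)
            resid = xj - xfit
            f_obs_j = self._marginal_f(Yc, Xc, others, j)
            n_ge = 0
            for pr in perms:
                Xp = Xc.copy()
                Xp[:, j] = xfit + resid[pr]
                if self._marginal_f(Yc, Xp, np.delete(Xp, j, axis=1), j) >= f_obs_j:
                    n_ge += 1
            pred_p[name] = (1 + n_ge) / (n_perm + 1)

        return {
            "model": float(p_model),
            "axes": [float(x) for x in axes_p],
            "predictors": pd.Series(pred_p),
        }

    def _marginal_f(self, Yc, X_full, X_reduced, j) -> float:
        n, p = X_full.shape
        df2 = n - p - 1
        bf, *_ = np.linalg.lstsq(X_full, Yc, rcond=None)
        full_fit = X_full @ bf
        ss_full = (full_fit**2).sum()
        if X_reduced.shape[1]:
            br, *_ = np.linalg.lstsq(X_reduced, Yc, rcond=None)
            ss_red = ((X_reduced @ br) ** 2).sum()
        else:
            ss_red = 0.0
        ss_res = ((Yc - full_fit) ** 2).sum()
        if ss_res <= 0 or df2 <= 0:
            return np.inf
        return (ss_full - ss_red) / (ss_res / df2)

    # -- candidate SNPs ----------------------------------------------------

    def candidate_snps(
        self,
        axis_pvalues: list[float],
        sd_multiplier: float = 1.0,
        alpha: float = 0.05,
        center: str = "mean",
    ) -> list[CandidateSnp]:
        """SNPs whose loading on a significant axis lies more than
        ``sd_multiplier`` SDs from the loading distribution's center
        (``center="mean"`` or ``"zero"``). Each candidate is attributed to the
        predictor with the highest squared correlation to its frequency
        column. Returns an empty list when no axis is significant."""
        out: list[CandidateSnp] = []
        pred = self.model.predictors
        for k, pk in enumerate(axis_pvalues):
            if not (pk == pk) or pk > alpha:  # NaN or non-significant
                continue
            load = self.snp_loadings.iloc[:, k].to_numpy()
            mu = load.mean() if center == "mean" else 0.0
            sd = load.std(ddof=1) if load.size > 1 else 0.0
            if sd == 0:
                continue
            hits = np.where(np.abs(load - mu) > sd_multiplier * sd)[0]
            for i in hits:
                y = self.model.response.iloc[:, i].to_numpy()
                r2s = {
                    c: np.corrcoef(y, pred[c].to_numpy())[0, 1] ** 2 for c in pred.columns
                }
                best = max(r2s, key=r2s.get)
                out.append(
                    CandidateSnp(
                        snp=str(self.model.response.columns[i]),
                        axis=k + 1,
                        loading=float(load[i]),
                        best_predictor=best,
                        r2=float(r2s[best]),
                    )
                )
        return out

    def summary(self) -> str:
        lines = [
            "Redundancy analysis",
            f"  samples: {self._Yc.shape[0]}, response features: {self._Yc.shape[1]}, "
            f"predictors: {self.model.predictors.shape[1]}",
            f"  proportion of variance constrained: {self.proportion_constrained:.4f}",
        ]
        for i, (ev, pct) in enumerate(zip(self.eigenvalues, self.axis_pct_of_constrained)):
            lines.append(f"  RDA{i + 1}: eigenvalue {ev:.4g} ({pct:.1f}% of constrained)")
        return "\n".join(lines)
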