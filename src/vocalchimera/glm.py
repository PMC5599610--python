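"""ROI BOLD simulation and GLM/group statistics.

The neural side of the pipeline: event trains from a
:class:`~vocalchimera.design.TrialSequence` are convolved with the
canonical double-gamma hemodynamic response function (HRF) to form a
design matrix (optionally with serially orthogonalized parametric
modulators in the order pitch, HNR, dominant scale, dominant rate,
spectral centroid); synthetic ROI time series are generated as
``y = X @ beta + AR(1) noise``; and the single-run fit plus the group
statistics of the study design (paired contrasts, 2x2
repeated-measures ANOVA, Greenhouse-Geisser-corrected one-way ANOVA)
are computed from the estimates.

The single-run model follows the statsmodels idiom: build a
:class:`RoiGlm` from data, call :meth:`RoiGlm.fit`, read estimates and
uncertainties off the returned :class:`RoiGlmResults` (``params``,
``bse``, ``tvalues``, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .design import TrialSequence

MODULATOR_ORDER = ("f0_hz", "hnr_db", "dom_scale_cpo", "dom_rate_hz", "centroid_hz")

# canonical double-gamma parameters: response delay 6 s, undershoot
# delay 16 s, unit dispersions, undershoot ratio 1/6, 32-s support
HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_PEAK_DISP_S = 1.0
HRF_UNDERSHOOT_DISP_S = 1.0
HRF_RATIO = 6.0
HRF_LENGTH_S = 32.0


def canonical_hrf(dt_s: float) -> np.ndarray:
    """Double-gamma HRF sampled every ``dt_s`` over 32 s, unit peak."""
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, HRF_LENGTH_S + dt_s / 2, dt_s)
    peak = gamma_dist.pdf(t, HRF_PEAK_DELAY_S / HRF_PEAK_DISP_S, scale=HRF_PEAK_DISP_S)
    under = gamma_dist.pdf(t, HRF_UNDERSHOOT_DELAY_S / HRF_UNDERSHOOT_DISP_S,
                           scale=HRF_UNDERSHOOT_DISP_S)
    h = peak - under / HRF_RATIO
    return h / h.max()


@dataclass
class DesignMatrix:
    """Named regressors sampled at the scan grid."""

    frame: pd.DataFrame
    tr_s: float
    condition_names: list[str]
    modulator_names: list[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(float)

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class RoiTimeSeries:
    values: np.ndarray
    tr_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series must be finite")

    def write_tsv(self, path) -> None:
        pd.DataFrame({"bold": self.values}).to_csv(path, sep="\t", index=False)


def build_design_matrix(
    seq: TrialSequence,
    modulators: pd.DataFrame | None = None,
    tr_s: float = 2.0,
    microtime_dt_s: float = 0.1,
    extra_scans: int = 0,
) -> DesignMatrix:
    """HRF-convolved condition regressors (one per trial_type, with
    repeat trials split into their own nuisance column) plus optional
    parametric modulators and an intercept.

    ``modulators`` is a feature table indexed by ``id`` (or with an
    ``id`` column) covering every stimulus in the sequence; its five
    descriptor columns are mean-centered over events, convolved, and
    serially orthogonalized against all earlier columns in the fixed
    order pitch, HNR, dominant scale, dominant rate, spectral centroid.
    """
    duration = seq.run_duration_s
    n_scans = int(np.ceil(duration / tr_s)) + extra_scans
    n_micro = int(np.ceil(n_scans * tr_s / microtime_dt_s)) + 1
    hrf = canonical_hrf(microtime_dt_s)
    scan_idx = np.round(np.arange(n_scans) * tr_s / microtime_dt_s).astype(int)

    conditions: dict[str, list] = {}
    for i, t in enumerate(seq.trials):
        name = f"{t.condition}_repeat" if t.is_repeat else t.condition
        conditions.setdefault(name, []).append(i)

    def convolved_column(onsets_s, weights=None) -> np.ndarray:
        train = np.zeros(n_micro)
        idx = np.round(np.asarray(onsets_s) / microtime_dt_s).astype(int)
        np.add.at(train, idx, 1.0 if weights is None else weights)
        return np.convolve(train, hrf)[:n_micro][scan_idx]

    cols: dict[str, np.ndarray] = {}
    cond_names = sorted(conditions)
    for name in cond_names:
        cols[name] = convolved_column([seq.trials[i].onset_s for i in conditions[name]])

    mod_names: list[str] = []
    if modulators is not None:
        table = modulators.set_index("id") if "id" in modulators.columns else modulators
        missing = [t.stimulus_id for t in seq.trials if t.stimulus_id not in table.index]
        if missing:
            raise KeyError(f"modulator table lacks rows for {sorted(set(missing))[:3]}...")
        onsets = [t.onset_s for t in seq.trials]
        ordered = ["intercept"] + cond_names
        base = [np.ones(n_scans)] + [cols[c] for c in cond_names]
        for feat in MODULATOR_ORDER:
            vals = np.array([table.loc[t.stimulus_id, feat] for t in seq.trials], float)
            col = convolved_column(onsets, weights=vals - vals.mean())
            # residualize against everything earlier in the listed order
            b = np.column_stack(base)
            col = col - b @ np.linalg.lstsq(b, col, rcond=None)[0]
            name = f"mod_{feat}"
            cols[name] = col
            mod_names.append(name)
            base.append(col)
            ordered.append(name)

    cols["intercept"] = np.ones(n_scans)
    frame = pd.DataFrame(cols)
    return DesignMatrix(frame=frame, tr_s=tr_s, condition_names=cond_names,
                        modulator_names=mod_names)


def simulate_roi_bold(
    design: DesignMatrix,
    true_betas: dict,
    noise_sd: float = 1.0,
    ar1_rho: float = 0.2,
    seed: int = 0,
) -> RoiTimeSeries:
    """``y = X @ beta + AR(1) Gaussian noise`` (stationary, marginal SD
    ``noise_sd``), deterministic given the seed."""
    unknown = set(true_betas) - set(design.frame.columns)
    if unknown:
        raise KeyError(f"betas refer to unknown columns {sorted(unknown)}")
    y = np.zeros(design.n_scans)
    for name, beta in true_betas.items():
        y += beta * design.frame[name].to_numpy(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        innov = rng.standard_normal(design.n_scans + 100)
        noise = lfilter([1.0], [1.0, -ar1_rho], innov)[100:]
        noise *= noise_sd * np.sqrt(1.0 - ar1_rho**2)
        y = y + noise
    return RoiTimeSeries(values=y, tr_s=design.tr_s,
                         meta=dict(noise_sd=noise_sd, ar1_rho=ar1_rho, seed=seed))


# ---------------------------------------------------------------------------
# single-run model


class RoiGlm:
    """Ordinary-least-squares GLM of one ROI time series on a design.

    Parameters
    ----------
    y : RoiTimeSeries or array-like
    X : DesignMatrix
    """

    def __init__(self, y, X: DesignMatrix):
        values = y.values if isinstance(y, RoiTimeSeries) else np.asarray(y, float)
        if values.size != X.n_scans:
            raise ValueError("time-series length must match the design")
        self.y = values
        self.design = X

    @classmethod
    def from_simulation(cls, design: DesignMatrix, true_betas: dict,
                        noise_sd: float = 1.0, ar1_rho: float = 0.2,
                        seed: int = 0) -> "RoiGlm":
        return cls(simulate_roi_bold(design, true_betas, noise_sd, ar1_rho, seed), design)

    def fit(self) -> "RoiGlmResults":
        X = self.design.matrix
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        params, _, _, _ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ params
        df_resid = X.shape[0] - rank
        scale = float(resid @ resid) / df_resid
        xtx_inv = np.linalg.inv(X.T @ X)
        bse = np.sqrt(scale * np.diag(xtx_inv))
        return RoiGlmResults(model=self, params=pd.Series(params, index=self.design.frame.columns),
                             bse=pd.Series(bse, index=self.design.frame.columns),
                             resid=resid, scale=scale, df_resid=df_resid, xtx_inv=xtx_inv)


@dataclass
class RoiGlmResults:
    model: RoiGlm
    params: pd.Series
    bse: pd.Series
    resid: np.ndarray
    scale: float            # residual variance
    df_resid: int
    xtx_inv: np.ndarray

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid),
                         index=self.params.index)

    def contrast(self, weights: dict) -> "ContrastResult":
        """t-test of a linear combination of the run's betas."""
        c = np.array([weights.get(name, 0.0) for name in self.params.index])
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(self.scale * c @ self.xtx_inv @ c))
        t = est / se
        return ContrastResult(estimate=est, t=t, df=self.df_resid,
                              p=float(2.0 * stats.t.sf(abs(t), self.df_resid)))

    def plot_fit(self, ax=None):
        """Observed vs fitted ROI time course (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = np.arange(self.model.y.size) * self.model.design.tr_s
        ax.plot(t, self.model.y, lw=0.6, label="observed", color="0.5")
        ax.plot(t, self.model.y - self.resid, lw=1.2, label="fitted")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("BOLD (a.u.)")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        lines = ["ROI GLM (OLS)",
                 f"  scans: {self.model.design.n_scans}, df_resid: {self.df_resid},"
                 f" resid var: {self.scale:.4g}", "",
                 f"  {'regressor':>20} {'beta':>10} {'SE':>9} {'t':>8} {'p':>9}"]
        for name in self.params.index:
            lines.append(f"  {name:>20} {self.params[name]:>10.4f} {self.bse[name]:>9.4f}"
                         f" {self.tvalues[name]:>8.2f} {self.pvalues[name]:>9.3g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# group statistics


@dataclass
class ContrastResult:
    estimate: float
    t: float
    df: int
    p: float
    degenerate: bool = False

    def __str__(self) -> str:
        flag = " (degenerate: zero within-subject variance)" if self.degenerate else ""
        return f"estimate = {self.estimate:.4g}, t({self.df}) = {self.t:.2f}, p = {self.p:.3g}{flag}"


@dataclass
class RmAnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    gg_epsilon: float | None = None

    def __str__(self) -> str:
        eps = f", GG eps = {self.gg_epsilon:.3f}" if self.gg_epsilon is not None else ""
        return f"{self.effect}: F({self.df1:.2f},{self.df2:.2f}) = {self.F:.2f}, p = {self.p:.3g}{eps}"


def group_contrast(estimates_a, estimates_b) -> ContrastResult:
    """Paired t-test on per-subject estimate differences (df = n - 1).

    ``estimates_b`` may be a 2-D (subjects x conditions) array, in
    which case each subject's mean over those conditions is used —
    the "A vs mean of several conditions" comparison.
    """
    a = np.asarray(estimates_a, float)
    b = np.asarray(estimates_b, float)
    if b.ndim == 2:
        b = b.mean(axis=1)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length 1-D per-subject estimates")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return ContrastResult(estimate=0.0, t=0.0, df=n - 1, p=1.0)
        return ContrastResult(estimate=float(d.mean()),
                              t=float(np.sign(d.mean()) * np.inf), df=n - 1,
                              p=0.0, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    return ContrastResult(estimate=float(d.mean()), t=t, df=n - 1,
                          p=float(2.0 * stats.t.sf(abs(t), n - 1)))


def rm_anova_2x2(data, factor_names: tuple[str, str] = ("temporal", "spectrum"),
                 cells: list[tuple[str, str]] | None = None) -> dict[str, RmAnovaResult]:
    """Two-factor repeated-measures ANOVA for 2x2 within-subject data.

    ``data`` is subjects x 4 conditions; ``cells`` gives the (factor1,
    factor2) level pair of each column, defaulting to the order
    (V,V), (V,I), (I,V), (I,I).  With 2-level factors each effect is a
    within-subject difference contrast: F(1, n-1) = t^2.
    """
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[1] != 4:
        raise ValueError("data must be subjects x 4 conditions")
    if np.any(~np.isfinite(data)):
        raise ValueError("missing cells are not allowed")
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    cells = cells or [("V", "V"), ("V", "I"), ("I", "V"), ("I", "I")]
    lv1 = sorted({c[0] for c in cells})
    lv2 = sorted({c[1] for c in cells})
    sign1 = np.array([1.0 if c[0] == lv1[0] else -1.0 for c in cells]) / 2.0
    sign2 = np.array([1.0 if c[1] == lv2[0] else -1.0 for c in cells]) / 2.0
    contrasts = {
        factor_names[0]: sign1,
        factor_names[1]: sign2,
        f"{factor_names[0]}:{factor_names[1]}": sign1 * sign2 * 4.0,
    }
    out = {}
    for effect, c in contrasts.items():
        scores = data @ c
        sd = scores.std(ddof=1)
        if sd == 0.0:
            f = 0.0 if scores.mean() == 0.0 else np.inf
            p = 1.0 if f == 0.0 else 0.0
        else:
            t = scores.mean() / (sd / np.sqrt(n))
            f = t**2
            p = float(stats.f.sf(f, 1, n - 1))
        out[effect] = RmAnovaResult(effect=effect, F=float(f), df1=1, df2=n - 1, p=p)
    return out


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample condition covariance,
    clipped to its mathematical bounds [1/(k-1), 1]."""
    data = np.asarray(data, float)
    n, k = data.shape
    s = np.cov(data, rowvar=False)
    center = np.eye(k) - np.ones((k, k)) / k
    sc = center @ s @ center
    tr = np.trace(sc)
    if tr <= 0:
        return 1.0
    eps = tr**2 / ((k - 1) * np.sum(sc * sc))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(data) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser
    correction (dfs multiplied by epsilon)."""
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("need subjects x k >= 3 conditions")
    n, k = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    f = (ss_cond / df1) / ms_err if ms_err > 0 else (0.0 if ss_cond == 0 else np.inf)
    eps = gg_epsilon(data)
    p = float(stats.f.sf(f, eps * df1, eps * df2)) if np.isfinite(f) else 0.0
    return RmAnovaResult(effect="condition", F=float(f), df1=eps * df1,
                         df2=eps * df2, p=p, gg_epsilon=eps)
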