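"""Generalised-least-squares MR estimators for correlated instruments.

Given a harmonised instrument set with variant-level exposure effects
``bx``, outcome effects ``by`` and an LD correlation matrix ``C``, the
estimators regress ``by`` on ``bx`` under the error covariance

    Omega = S C S,        S = diag(se_y),

which reduces to the textbook inverse-variance-weighted (IVW) estimator
when instruments are independent (``C = I``) and otherwise corrects for
residual LD among clumped instruments. Two mean models are fitted:

* IVW: ``by = theta * bx`` (no intercept);
* MR-Egger: ``by = alpha + theta * bx`` with all variants oriented so
  ``bx >= 0``; the free intercept ``alpha`` absorbs directional
  pleiotropy.

Heterogeneity is summarised by the generalised Q statistic
``(by - X b)' Omega^{-1} (by - X b)``. Variants that dominate the fit
(leverage above three times the mean) or misfit it (whitened squared
residual above the chi-square cut 10.83, the 1-df critical value at
p = 0.001) are excluded once and the model refitted. Model choice
between IVW and Egger follows goodness-of-fit versus parsimony: Egger is
selected only when its Q reduction exceeds the 1-df chi-square critical
value. Analyses retaining fewer than six variants at any fitting stage
are discarded rather than reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import InstrumentSet, LDMatrix, SummaryStatSet
from .instruments import InstrumentConfig, select_instruments

#: Chi-square(1) critical value at two-sided p = 0.001; outlier cut.
OUTLIER_CHISQ = 10.83

#: Minimum variants for a reportable MR analysis.
MIN_VARIANTS = 6


@dataclass
class MRConfig:
    """Estimator settings; defaults are the pipeline's reporting defaults."""

    min_variants: int = MIN_VARIANTS
    leverage_mult: float = 3.0
    chisq_cut: float = OUTLIER_CHISQ
    selection_alpha: float = 0.05
    max_condition: float = 1e8   # LD regularisation trigger
    prune_passes: int = 1


@dataclass
class MRFit:
    """One exposure-outcome MR result.

    ``slope`` is the causal effect per 1 SD exposure (log-odds for
    disease outcomes; ``odds_ratio`` exponentiates it). ``slope_se`` is
    the reported standard error after multiplicative random-effects
    inflation by sqrt(max(1, Q/Q_df)); ``slope_se_fixed`` is the plain
    GLS standard error.
    """

    exposure_id: str
    outcome_id: str
    model: str
    slope: float
    slope_se: float
    slope_se_fixed: float
    ci95: tuple[float, float]
    pval: float
    Q: float
    Q_df: int
    n_variants_used: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    excluded: list[tuple[str, str]] = field(default_factory=list)
    leverage: np.ndarray | None = None
    std_residual_sq: np.ndarray | None = None
    selection_stat: float | None = None
    ld_shrinkage: float = 0.0
    flags: list[str] = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.slope))

    @property
    def or_ci95(self) -> tuple[float, float]:
        return float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1]))


@dataclass
class DiscardedAnalysis:
    """Marker for an MR analysis discarded before reporting."""

    exposure_id: str
    outcome_id: str
    reason: str
    n_variants: int


def _regularise(C: np.ndarray, max_condition: float):
    """Shrink off-diagonals toward zero until the condition number is
    acceptable; returns (C_reg, shrinkage lambda in [0, 1])."""
    lam = 0.0
    C_reg = C
    eye = np.eye(C.shape[0])
    while lam < 1.0:
        C_reg = (1 - lam) * C + lam * eye
        eigvals = np.linalg.eigvalsh(C_reg)
        if eigvals[0] > 0 and eigvals[-1] / eigvals[0] < max_condition:
            return C_reg, lam
        lam = 0.01 if lam == 0.0 else lam * 2
    return eye, 1.0


def gls_fit(
    instr: InstrumentSet,
    model: str = "IVW",
    config: MRConfig | None = None,
) -> MRFit:
    """Fit GLS-IVW (``model="IVW"``) or GLS-MR-Egger (``model="Egger"``).

    For Egger, every variant is oriented so its exposure effect is
    non-negative (``bx``, ``by`` jointly sign-flipped), the conventional
    orientation making the intercept identifiable. Raises
    ``np.linalg.LinAlgError`` naming near-duplicate variants when the
    weight matrix is singular beyond repair.
    """
    config = config or MRConfig()
    if model not in ("IVW", "Egger"):
        raise ValueError(f"unknown model {model!r}")
    k = len(instr)
    if k < (2 if model == "IVW" else 3):
        raise ValueError(f"too few variants ({k}) for {model}")

    bx = instr.variants["bx"].to_numpy(dtype=float)
    by = instr.variants["by"].to_numpy(dtype=float)
    se_y = instr.variants["se_y"].to_numpy(dtype=float)
    C_raw = instr.ld.r
    if model == "Egger":
        # orient every variant so bx >= 0; re-orienting an allele also
        # flips the sign of its LD correlation with every other variant
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        bx, by = bx * flip, by * flip
        C_raw = C_raw * np.outer(flip, flip)

    C, lam = _regularise(C_raw, config.max_condition)
    if not np.all(np.isfinite(C)):
        raise np.linalg.LinAlgError("non-finite LD matrix")
    omega = (se_y[:, None] * C) * se_y[None, :]
    try:
        cho = linalg.cho_factor(omega)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - regularised above
        dup = _near_duplicates(instr.ld)
        raise np.linalg.LinAlgError(
            f"singular weight matrix; near-duplicate variants: {dup}"
        ) from exc

    X = bx[:, None] if model == "IVW" else np.column_stack([np.ones(k), bx])
    Wi_X = linalg.cho_solve(cho, X)
    Wi_y = linalg.cho_solve(cho, by)
    xtwx = X.T @ Wi_X
    xtwy = X.T @ Wi_y
    xtwx_inv = np.linalg.inv(xtwx)
    coef = xtwx_inv @ xtwy
    resid = by - X @ coef
    Q = float(resid @ linalg.cho_solve(cho, resid))
    Q_df = k - X.shape[1]

    # whitened residuals: z = L^{-1} e with Omega = L L'; sum(z^2) = Q
    L = linalg.cholesky(omega, lower=True)
    z = linalg.solve_triangular(L, resid, lower=True)
    std_residual_sq = z**2
    # leverage: diagonal of X (X' Omega^{-1} X)^{-1} X' Omega^{-1}
    leverage = np.einsum("ij,jk,ik->i", X, xtwx_inv, Wi_X)

    slope_idx = 0 if model == "IVW" else 1
    slope = float(coef[slope_idx])
    se_fixed = float(np.sqrt(xtwx_inv[slope_idx, slope_idx]))
    inflation = np.sqrt(max(1.0, Q / Q_df)) if Q_df > 0 else 1.0
    slope_se = se_fixed * inflation
    ci = (slope - 1.96 * slope_se, slope + 1.96 * slope_se)
    pval = float(np.clip(2 * stats.norm.sf(abs(slope) / slope_se),
                         np.finfo(float).tiny, 1.0))

    fit = MRFit(
        exposure_id=instr.exposure_id,
        outcome_id=instr.outcome_id,
        model=model,
        slope=slope,
        slope_se=slope_se,
        slope_se_fixed=se_fixed,
        ci95=ci,
        pval=pval,
        Q=Q,
        Q_df=Q_df,
        n_variants_used=k,
        leverage=leverage,
        std_residual_sq=std_residual_sq,
        ld_shrinkage=lam,
    )
    if model == "Egger":
        int_se = float(np.sqrt(xtwx_inv[0, 0])) * inflation
        fit.intercept = float(coef[0])
        fit.intercept_se = int_se
        fit.intercept_p = float(np.clip(
            2 * stats.norm.sf(abs(coef[0]) / int_se), np.finfo(float).tiny, 1.0))
    return fit


def _near_duplicates(ld: LDMatrix, r_cut: float = 0.999) -> list[tuple[str, str]]:
    pairs = []
    k = len(ld)
    for i in range(k):
        for j in range(i + 1, k):
            if abs(ld.r[i, j]) >= r_cut:
                pairs.append((ld.variant_ids[i], ld.variant_ids[j]))
    return pairs


def leverage_outlier_prune(
    fit: MRFit,
    instr: InstrumentSet,
    config: MRConfig | None = None,
):
    """Exclude high-leverage and outlying variants, then refit once.

    A variant is excluded when its leverage exceeds
    ``leverage_mult x mean leverage`` or its whitened squared residual
    exceeds ``chisq_cut``. Returns ``(pruned InstrumentSet, refit MRFit)``
    with exclusions logged on the refit, or a
    :class:`DiscardedAnalysis` in the second slot when pruning leaves
    fewer than ``min_variants`` variants.
    """
    config = config or MRConfig()
    if fit.leverage is None or fit.std_residual_sq is None:
        raise ValueError("fit lacks diagnostics; refit with gls_fit first")
    ids = list(instr.variants["variant_id"])
    mean_h = float(np.mean(fit.leverage))
    excluded: list[tuple[str, str]] = []
    for vid, h, s in zip(ids, fit.leverage, fit.std_residual_sq):
        if h > config.leverage_mult * mean_h:
            excluded.append((vid, "leverage"))
        elif s > config.chisq_cut:
            excluded.append((vid, "outlier"))
    if not excluded:
        refit = gls_fit(instr, fit.model, config)
        refit.excluded = []
        return instr, refit
    drop = {v for v, _ in excluded}
    keep = [v for v in ids if v not in drop]
    if len(keep) < config.min_variants:
        return instr, DiscardedAnalysis(
            instr.exposure_id, instr.outcome_id,
            "insufficient_instruments", len(keep),
        )
    pruned = InstrumentSet(
        exposure_id=instr.exposure_id,
        outcome_id=instr.outcome_id,
        variants=instr.variants.set_index("variant_id").loc[keep].reset_index(),
        ld=instr.ld.restrict(keep),
        exclusion_log=instr.exclusion_log
        + [(v, "prune", r) for v, r in excluded],
    )
    refit = gls_fit(pruned, fit.model, config)
    refit.excluded = excluded
    return pruned, refit


def select_model(fit_ivw: MRFit, fit_egger: MRFit | None,
                 alpha: float = 0.05) -> MRFit:
    """Choose between IVW and MR-Egger by goodness-of-fit vs parsimony.

    Egger is selected iff its one extra parameter buys a Q reduction
    exceeding the chi-square(1) critical value at ``alpha``; otherwise
    the more parsimonious IVW is kept. The decision statistic
    ``Q_ivw - Q_egger`` is recorded on the returned fit.
    """
    if fit_egger is None:
        fit_ivw.flags.append("egger_unfit")
        return fit_ivw
    crit = stats.chi2.ppf(1 - alpha, 1)
    delta = fit_ivw.Q - fit_egger.Q
    chosen = fit_egger if delta > crit else fit_ivw
    chosen.selection_stat = float(delta)
    return chosen


def run_mr(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: LDMatrix,
    instrument_config: InstrumentConfig | None = None,
    mr_config: MRConfig | None = None,
):
    """Full single-pair MR: select instruments, fit, prune, choose model.

    Returns the selected :class:`MRFit` or a :class:`DiscardedAnalysis`
    whenever fewer than six variants remain at any fitting stage (or no
    variants overlap between exposure and outcome).
    """
    mr_config = mr_config or MRConfig()
    instr = select_instruments(exposure, outcome, ld, instrument_config)
    if len(instr) == 0:
        reason = ("no_overlap"
                  if any(r == "no_overlap" for _, _, r in instr.exclusion_log)
                  else "fewer_than_six")
        return DiscardedAnalysis(exposure.trait_id, outcome.trait_id, reason, 0)
    if len(instr) < mr_config.min_variants:
        return DiscardedAnalysis(
            exposure.trait_id, outcome.trait_id, "fewer_than_six", len(instr)
        )

    fit_ivw = gls_fit(instr, "IVW", mr_config)
    pruned, refit_ivw = leverage_outlier_prune(fit_ivw, instr, mr_config)
    if isinstance(refit_ivw, DiscardedAnalysis):
        return refit_ivw

    refit_egger = None
    if len(pruned) >= max(3, mr_config.min_variants):
        fit_egger = gls_fit(pruned, "Egger", mr_config)
        refit_egger = fit_egger
    selected = select_model(refit_ivw, refit_egger, mr_config.selection_alpha)
    selected.excluded = refit_ivw.excluded
    return selected


def table_to_fits(df: pd.DataFrame) -> list[MRFit]:
    """Rebuild reportable MRFit records from a results table.

    Discarded analyses are dropped; per-variant diagnostics are not
    round-tripped (the table stores summaries only).
    """
    fits = []
    for row in df.itertuples(index=False):
        reason = getattr(row, "discard_reason", "")
        if isinstance(reason, str) and reason:
            continue
        if not isinstance(reason, str) and not pd.isna(reason):
            continue
        fits.append(MRFit(
            exposure_id=row.exposure_id, outcome_id=row.outcome_id,
            model=row.model, slope=row.slope, slope_se=row.se,
            slope_se_fixed=row.se, ci95=(row.ci_lo, row.ci_hi),
            pval=row.pval, Q=row.Q, Q_df=int(row.Q_df),
            n_variants_used=int(row.n_variants),
        ))
    return fits


def fits_to_table(results: list) -> pd.DataFrame:
    """Flatten MRFit / DiscardedAnalysis objects into a results table."""
    rows = []
    for res in results:
        if isinstance(res, DiscardedAnalysis):
            rows.append({
                "exposure_id": res.exposure_id,
                "outcome_id": res.outcome_id,
                "model": "",
                "slope": np.nan, "se": np.nan,
                "odds_ratio": np.nan,
                "ci_lo": np.nan, "ci_hi": np.nan, "pval": np.nan,
                "Q": np.nan, "Q_df": 0,
                "n_variants": res.n_variants,
                "n_excluded_leverage": 0, "n_excluded_outlier": 0,
                "discard_reason": res.reason,
            })
        else:
            rows.append({
                "exposure_id": res.exposure_id,
                "outcome_id": res.outcome_id,
                "model": res.model,
                "slope": res.slope, "se": res.slope_se,
                "odds_ratio": res.odds_ratio,
                "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                "pval": res.pval,
                "Q": res.Q, "Q_df": res.Q_df,
                "n_variants": res.n_variants_used,
                "n_excluded_leverage": sum(
                    1 for _, r in res.excluded if r == "leverage"),
                "n_excluded_outlier": sum(
                    1 for _, r in res.excluded if r == "outlier"),
                "discard_reason": "",
            })
    return pd.DataFrame(rows)
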