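"""Toxicity association: proportional-odds models and AIC-stepwise selection.

Breast toxicity (pain, oedema, atrophy, induration) is graded 0–3 at three
timepoints, separately by clinician (CTCAE-style) and patient (BR23-style);
the analysed grade is the maximum of the two reports.  For each
endpoint × timepoint cell the workflow is:

1. screen candidate variables for pairwise collinearity (|Pearson r| >= 0.9
   drops one of the pair);
2. fit a baseline proportional-odds model with the fixed clinical
   covariates (e.g. age, breast volume, boost);
3. forward-stepwise add composition/dose candidates, accepting the largest
   AIC decrease each step, never removing baseline variables;
4. optionally repeat backward from the full model and flag agreement.

Models are ordinal logistic regressions (proportional odds / cumulative
logit) fitted by maximum likelihood; AIC = 2k − 2·logL with k counting
slopes and cutpoints.  Selection itself has no randomness: it is a
deterministic function of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel

ENDPOINTS = ("pain", "oedema", "atrophy", "induration")
TIMEPOINTS = ("post_rt", "year1", "year2")
SOURCES = ("cro", "pro")
COLLINEARITY_THRESHOLD = 0.9
GRADE_LEVELS = (0, 1, 2, 3)


class FitError(RuntimeError):
    """Model could not be fitted (separation, non-convergence, degenerate outcome)."""


# ---------------------------------------------------------------------------
# outcome merging


def merge_outcomes(cro, pro):
    """Merged grade = max of the available clinician/patient grades.

    Accepts scalars or aligned pandas Series (NaN = missing).  Returns the
    merged grade(s) and a provenance marker per observation:
    ``cro`` / ``pro`` / ``tie`` / ``missing``.
    """
    cro_s = pd.Series(cro, dtype="float64") if not isinstance(cro, pd.Series) else cro.astype("float64")
    pro_s = pd.Series(pro, dtype="float64") if not isinstance(pro, pd.Series) else pro.astype("float64")
    merged = pd.concat([cro_s, pro_s], axis=1).max(axis=1)  # NaN-skipping max
    provenance = pd.Series("missing", index=merged.index, dtype=object)
    both = ~cro_s.isna() & ~pro_s.isna()
    provenance[both & (cro_s > pro_s)] = "cro"
    provenance[both & (pro_s > cro_s)] = "pro"
    provenance[both & (pro_s == cro_s)] = "tie"
    provenance[~cro_s.isna() & pro_s.isna()] = "cro"
    provenance[cro_s.isna() & ~pro_s.isna()] = "pro"
    return merged, provenance


def merge_outcome_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add merged ``{endpoint}_{timepoint}`` columns from the ``_cro``/``_pro``
    pairs present in a cohort table, plus max-over-time ``{endpoint}_max``."""
    out = df.copy()
    for ep in ENDPOINTS:
        cols = []
        for tp in TIMEPOINTS:
            c, p = f"{ep}_{tp}_cro", f"{ep}_{tp}_pro"
            if c in df.columns and p in df.columns:
                merged, _ = merge_outcomes(df[c], df[p])
                out[f"{ep}_{tp}"] = merged
                cols.append(f"{ep}_{tp}")
        if cols:
            out[f"{ep}_max"] = out[cols].max(axis=1)
    return out


# ---------------------------------------------------------------------------
# collinearity screen


def collinearity_filter(
    df: pd.DataFrame,
    variables: list[str],
    threshold: float = COLLINEARITY_THRESHOLD,
    scorer=None,
) -> tuple[list[str], list[dict]]:
    """Drop one variable from every pair with |Pearson r| >= threshold.

    ``scorer(variable) -> float`` (lower is better, e.g. univariable AIC for
    the current endpoint) decides which member of a flagged pair to keep;
    without a scorer the earlier-listed variable is kept.  Zero-variance
    variables are dropped outright.  Returns the retained list (input order)
    and a record of every drop decision.
    """
    decisions: list[dict] = []
    usable = []
    for v in variables:
        x = df[v].dropna()
        if x.nunique() <= 1:
            decisions.append({"dropped": v, "kept": None, "r": np.nan, "reason": "zero variance"})
        else:
            usable.append(v)
    corr = df[usable].corr(method="pearson")
    dropped: set[str] = set()
    scores = {v: (scorer(v) if scorer else i) for i, v in enumerate(usable)}
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            if a in dropped or b in dropped:
                continue
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                keep, drop = (a, b) if scores[a] <= scores[b] else (b, a)
                dropped.add(drop)
                decisions.append(
                    {"dropped": drop, "kept": keep, "r": float(r), "reason": f"|r|>={threshold}"}
                )
    retained = [v for v in usable if v not in dropped]
    return retained, decisions


# ---------------------------------------------------------------------------
# proportional-odds fitting


@dataclass(frozen=True)
class OrdinalFit:
    """A fitted proportional-odds (cumulative logit) model."""

    outcome: str
    covariates: tuple[str, ...]
    params: pd.Series  # slope coefficients only
    bse: pd.Series
    pvalues: pd.Series
    cutpoints: np.ndarray  # strictly increasing intercepts
    log_likelihood: float
    aic: float
    n_used: int
    converged: bool

    @property
    def n_parameters(self) -> int:
        return len(self.params) + len(self.cutpoints)


def fit_ordinal(
    df: pd.DataFrame,
    outcome: str,
    covariates: list[str] | tuple[str, ...],
    warn_obs_per_param: int = 10,
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit on complete cases.

    Raises :class:`FitError` for degenerate outcomes (fewer than two
    observed levels) or optimizer failure; warns when there are fewer than
    ``warn_obs_per_param`` complete cases per parameter.
    """
    covariates = tuple(covariates)
    cols = [outcome, *covariates]
    data = df[cols].dropna()
    y = data[outcome].astype(int)
    levels = np.sort(y.unique())
    if len(levels) < 2:
        raise FitError(f"outcome '{outcome}' has a single observed level ({levels.tolist()})")
    n_params = len(covariates) + len(levels) - 1
    if len(data) < warn_obs_per_param * n_params:
        warnings.warn(
            f"{len(data)} complete cases for {n_params} parameters in "
            f"'{outcome}' model; estimates may be unstable",
            stacklevel=2,
        )
    exog = data[list(covariates)].astype(float) if covariates else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y, exog, distr="logit")
        try:
            res = model.fit(method="bfgs", maxiter=200, disp=False)
        except Exception as exc:  # singular Hessian, separation, ...
            raise FitError(f"ordinal fit failed for '{outcome}': {exc}") from exc
    converged = bool(res.mle_retvals.get("converged", False))
    k_slopes = len(covariates)
    params = pd.Series(res.params[:k_slopes], index=list(covariates), dtype=float)
    bse = pd.Series(res.bse[:k_slopes], index=list(covariates), dtype=float)
    pvalues = pd.Series(res.pvalues[:k_slopes], index=list(covariates), dtype=float)
    # statsmodels parametrizes thresholds as (t0, log-increments); transform back
    raw = np.asarray(res.params[k_slopes:], dtype=float)
    cutpoints = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))]) if len(raw) else raw
    llf = float(res.llf)
    aic = 2.0 * (k_slopes + len(cutpoints)) - 2.0 * llf
    if not np.all(np.isfinite(bse)):
        converged = False
    return OrdinalFit(
        outcome=outcome,
        covariates=covariates,
        params=params,
        bse=bse,
        pvalues=pvalues,
        cutpoints=cutpoints,
        log_likelihood=llf,
        aic=aic,
        n_used=int(len(data)),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# stepwise selection


@dataclass(frozen=True)
class SelectionStep:
    action: str  # "add" or "remove"
    variable: str
    aic_before: float
    aic_after: float
    accepted: bool
    note: str = ""


@dataclass(frozen=True)
class SelectionTrace:
    direction: str
    baseline_aic: float
    steps: tuple[SelectionStep, ...]
    final_variables: tuple[str, ...]


def _try_fit(df, outcome, covariates) -> OrdinalFit | None:
    try:
        fit = fit_ordinal(df, outcome, covariates)
    except FitError:
        return None
    return fit if fit.converged else None


def stepwise_aic(
    df: pd.DataFrame,
    outcome: str,
    baseline: list[str],
    candidates: list[str],
    direction: str = "forward",
) -> tuple[SelectionTrace, OrdinalFit]:
    """Greedy AIC-stepwise selection over ``candidates`` with ``baseline``
    covariates held fixed.

    Forward: start from the baseline model and add the candidate giving the
    largest AIC decrease until none decreases it.  Backward: start from
    baseline + all candidates and remove the candidate whose removal lowers
    AIC most, until no removal lowers it.  Candidates whose fit fails are
    skipped with a note in the trace.  Complete cases are fixed to rows
    observed on baseline + all candidates so AICs are comparable.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    baseline = list(baseline)
    candidates = [c for c in candidates if c not in baseline]
    data = df[[outcome, *baseline, *candidates]].dropna()
    base_fit = _try_fit(data, outcome, baseline)
    if base_fit is None:
        raise FitError(f"baseline model for '{outcome}' failed to converge")
    steps: list[SelectionStep] = []

    if direction == "forward":
        selected: list[str] = []
        current = base_fit
        while True:
            trials = []
            for cand in candidates:
                if cand in selected:
                    continue
                fit = _try_fit(data, outcome, baseline + selected + [cand])
                if fit is None:
                    steps.append(
                        SelectionStep("add", cand, current.aic, np.nan, False, "fit failed")
                    )
                    continue
                trials.append((fit.aic, cand, fit))
            if not trials:
                break
            trials.sort(key=lambda t: (t[0], t[1]))
            best_aic, best_var, best_fit = trials[0]
            accepted = best_aic < current.aic
            steps.append(SelectionStep("add", best_var, current.aic, best_aic, accepted))
            if not accepted:
                break
            selected.append(best_var)
            current = best_fit
        final_vars = tuple(baseline + selected)
        final_fit = current
    else:
        selected = list(candidates)
        current = _try_fit(data, outcome, baseline + selected)
        if current is None:
            raise FitError(f"full model for '{outcome}' failed to converge")
        while selected:
            trials = []
            for cand in selected:
                rest = [c for c in selected if c != cand]
                fit = _try_fit(data, outcome, baseline + rest)
                if fit is None:
                    steps.append(
                        SelectionStep("remove", cand, current.aic, np.nan, False, "fit failed")
                    )
                    continue
                trials.append((fit.aic, cand, fit))
            if not trials:
                break
            trials.sort(key=lambda t: (t[0], t[1]))
            best_aic, best_var, best_fit = trials[0]
            accepted = best_aic < current.aic
            steps.append(SelectionStep("remove", best_var, current.aic, best_aic, accepted))
            if not accepted:
                break
            selected.remove(best_var)
            current = best_fit
        final_vars = tuple(baseline + selected)
        final_fit = current

    trace = SelectionTrace(
        direction=direction,
        baseline_aic=base_fit.aic,
        steps=tuple(steps),
        final_variables=final_vars,
    )
    return trace, final_fit


# ---------------------------------------------------------------------------
# endpoint sweep


def endpoint_sweep(
    df: pd.DataFrame,
    baseline: list[str],
    candidates: list[str],
    endpoints: tuple[str, ...] = ENDPOINTS,
    timepoints: tuple[str, ...] = TIMEPOINTS,
    check_backward: bool = True,
    collinearity_threshold: float = COLLINEARITY_THRESHOLD,
) -> pd.DataFrame:
    """Run the full selection workflow per endpoint × timepoint cell.

    ``timepoints`` may include ``"max"`` to analyse the maximum grade over
    time (the severity summary used when a single grade per patient is
    wanted).  Returns one row per cell with baseline/best AIC, the selected
    variables, their coefficients and two-tier significance flags
    (p<0.05 → ``*``, p<0.001 → ``**``), and a forward/backward agreement
    flag.  Cells whose outcome is degenerate are reported with a skip
    reason instead of a model.
    """
    rows = []
    for ep in endpoints:
        for tp in timepoints:
            outcome = f"{ep}_{tp}"
            row: dict = {"endpoint": ep, "timepoint": tp}
            if outcome not in df.columns:
                row["skipped"] = "outcome column missing"
                rows.append(row)
                continue
            cell = df[[outcome, *baseline, *candidates]].dropna()
            observed = cell[outcome].nunique()
            if observed < 2:
                row["skipped"] = "single level"
                rows.append(row)
                continue

            def _uni_aic(var, _outcome=outcome, _cell=cell):
                fit = _try_fit(_cell, _outcome, [var])
                return fit.aic if fit is not None else np.inf

            retained, decisions = collinearity_filter(
                cell, candidates, threshold=collinearity_threshold, scorer=_uni_aic
            )
            try:
                trace, fit = stepwise_aic(cell, outcome, baseline, retained, "forward")
            except FitError as exc:
                row["skipped"] = str(exc)
                rows.append(row)
                continue
            selected = [v for v in trace.final_variables if v not in baseline]
            coef_str = []
            for var in fit.covariates:
                p = fit.pvalues[var]
                stars = "**" if p < 0.001 else ("*" if p < 0.05 else "")
                coef_str.append(f"{var}={fit.params[var]:+.3f}{stars}")
            row.update(
                {
                    "skipped": "",
                    "n": fit.n_used,
                    "baseline_aic": trace.baseline_aic,
                    "best_aic": fit.aic,
                    "selected": ";".join(selected),
                    "coefficients": ";".join(coef_str),
                    "n_collinearity_dropped": sum(1 for d in decisions if d["kept"]),
                }
            )
            if check_backward:
                try:
                    btrace, _ = stepwise_aic(cell, outcome, baseline, retained, "backward")
                    row["forward_backward_agree"] = set(btrace.final_variables) == set(
                        trace.final_variables
                    )
                except FitError:
                    row["forward_backward_agree"] = None
            rows.append(row)
    return pd.DataFrame(rows)
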