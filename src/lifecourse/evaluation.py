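"""Evaluation metrics: incidence, calibration, stratified AUC, bias tests.

The metric stack mirrors how rate-emitting trajectory models are
validated against registry data:

* predicted annual risks derive from log-rates via the exponential
  waiting-time identity ``P(T < 1y) = 1 - exp(-rate * 365.25)``;
* observed incidence is counted in yearly age bins with an at-risk
  denominator shrinking by cumulative deaths (censoring);
* discrimination is age- and sex-stratified: AUCs in 5-year brackets
  (ages 50-80) are averaged, with DeLong bracket variances combined as
  ``sigma^2 = (1/n^2) sum sigma_i^2``;
* subgroup bias is a chi-square on precision-weighted standardized
  residuals of subgroup AUCs;
* calibration groups predicted annual incidences into geometric risk
  bins (factor 5 from 1e-6 to 1) against observed rates;
* the longitudinal harness truncates histories at a cutoff age, skips a
  data gap, and scores outcomes in the following horizon window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .trajectory import DAYS_PER_YEAR, Trajectory
from .vocab import TokenVocabulary

DAYS_PER_ANNUM = 365.25


# ---------------------------------------------------------------------
# rate -> risk
# ---------------------------------------------------------------------

def annual_risk_from_logit(logit):
    """P(event within a year) = 1 - exp(-exp(logit) * 365.25).

    Vectorized; ``-inf`` maps to 0, ``+inf`` to 1; monotone throughout.
    """
    logit = np.asarray(logit, dtype=float)
    with np.errstate(over="ignore"):
        out = -np.expm1(-np.exp(logit) * DAYS_PER_ANNUM)
    return out if out.ndim else float(out)


def annual_risk_from_rate(rate_per_day):
    rate = np.asarray(rate_per_day, dtype=float)
    out = -np.expm1(-rate * DAYS_PER_ANNUM)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------
# observed incidence
# ---------------------------------------------------------------------

def observed_incidence(
    cohort: list[Trajectory],
    vocab: TokenVocabulary,
    token: int,
    age_bin_years: float = 1.0,
    max_age_years: float = 100.0,
) -> pd.DataFrame:
    """Per-sex incidence of ``token`` in yearly age bins.

    The at-risk denominator for a bin is the number of probands of that
    sex minus the cumulative deaths before the bin start, accounting
    for censoring by death.  Returns columns (sex, age_years, events,
    at_risk, incidence) where incidence is events per person-year bin.
    """
    if not cohort:
        raise ValueError("empty cohort")
    female, male = vocab.sex_indices
    edges = np.arange(0.0, max_age_years + age_bin_years, age_bin_years)
    rows = []
    for sex_tok, sex_name in ((female, "female"), (male, "male")):
        members = [t for t in cohort if t.sex_token(vocab) == sex_tok]
        n = len(members)
        event_ages, death_ages = [], []
        for t in members:
            hits = np.flatnonzero(t.tokens == token)
            if hits.size:
                event_ages.append(t.ages[hits[0]] / DAYS_PER_YEAR)
            d = t.death_age(vocab)
            if d is not None:
                death_ages.append(d / DAYS_PER_YEAR)
        ev = np.histogram(event_ages, bins=edges)[0]
        deaths = np.histogram(death_ages, bins=edges)[0]
        cum_dead = np.concatenate([[0], np.cumsum(deaths)[:-1]])
        at_risk = n - cum_dead
        with np.errstate(invalid="ignore", divide="ignore"):
            inc = np.where(at_risk > 0, ev / np.maximum(at_risk, 1), 0.0)
        for k in range(len(ev)):
            rows.append((sex_name, edges[k], ev[k], at_risk[k], inc[k]))
    return pd.DataFrame(
        rows, columns=["sex", "age_years", "events", "at_risk", "incidence"]
    )


# ---------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------

def calibration_bin_edges() -> np.ndarray:
    """Geometric risk-bin edges, factor 5 from 1e-6 up to 1."""
    edges = [1e-6]
    while edges[-1] < 1.0:
        edges.append(edges[-1] * 5.0)
    edges[-1] = 1.0
    return np.array(edges)


def calibration_curve(
    predicted_annual: np.ndarray,
    is_case: np.ndarray,
    band_years: float = 5.0,
) -> pd.DataFrame:
    """Bin predicted annual incidences and compare with observed rates.

    ``is_case`` marks case datapoints in the case/control design (cases
    accrued over ``band_years``-wide age bands, one random control per
    other proband in the same band); the observed annual incidence in a
    bin is the case fraction divided by the band width.  Empty bins are
    omitted.
    """
    predicted_annual = np.asarray(predicted_annual, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    edges = calibration_bin_edges()
    which = np.digitize(predicted_annual, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(sel.sum()),
                "n_cases": int(is_case[sel].sum()),
                "predicted_mean": float(predicted_annual[sel].mean()),
                "observed_annual": float(is_case[sel].mean() / band_years),
            }
        )
    return pd.DataFrame(rows)


def case_control_datapoints(
    cohort: list[Trajectory],
    vocab: TokenVocabulary,
    token: int,
    predict_fn,
    band_years: float = 5.0,
    max_age_years: float = 100.0,
    max_gap_years: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Case/control predicted-risk datapoints for one token.

    Cases of ``token`` are collected per ``band_years`` age band; for
    every other proband under observation in the band one control age
    is drawn uniformly.  The prediction is evaluated at the last event
    preceding the index age, provided it lies within ``max_gap_years``.
    ``predict_fn(trajectory_prefix, token) -> annual risk``.

    Returns columns (person_id, sex, age_years, is_case, predicted).
    """
    rng = np.random.default_rng(seed)
    female, male = vocab.sex_indices
    edges = np.arange(0.0, max_age_years + band_years, band_years)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lo_d, hi_d = lo * DAYS_PER_YEAR, hi * DAYS_PER_YEAR
        band_cases = []
        others = []
        for traj in cohort:
            hits = np.flatnonzero(traj.tokens == token)
            case_age = traj.ages[hits[0]] if hits.size else None
            if case_age is not None and lo_d <= case_age < hi_d:
                band_cases.append((traj, case_age, True))
            else:
                death = traj.death_age(vocab)
                end = min(traj.window_end, death if death is not None else np.inf)
                if end > lo_d and traj.window_start < hi_d:
                    others.append((traj, min(end, hi_d), lo_d))
        if not band_cases:
            continue
        for traj, end, start in others:
            band_cases.append((traj, rng.uniform(start, end), False))
        for traj, index_age, is_case in band_cases:
            before = np.flatnonzero(traj.ages < index_age)
            if before.size == 0:
                continue
            last = before[-1]
            if index_age - traj.ages[last] > max_gap_years * DAYS_PER_YEAR:
                continue
            prefix = Trajectory(
                traj.person_id,
                traj.ages[: last + 1],
                traj.tokens[: last + 1],
                traj.window_start,
                traj.window_end,
            )
            sex = "male" if traj.sex_token(vocab) == male else "female"
            rows.append(
                {
                    "person_id": traj.person_id,
                    "sex": sex,
                    "age_years": index_age / DAYS_PER_YEAR,
                    "is_case": is_case,
                    "predicted": float(predict_fn(prefix, token)),
                }
            )
    return pd.DataFrame(
        rows, columns=["person_id", "sex", "age_years", "is_case", "predicted"]
    )


# ---------------------------------------------------------------------
# AUC machinery
# ---------------------------------------------------------------------

def delong_auc_variance(case_scores: np.ndarray, control_scores: np.ndarray):
    """DeLong's estimator: (AUC, variance) for one bracket.

    Placement values: V10_i = mean over controls of the tie-corrected
    indicator, V01_j symmetric; the variance combines their empirical
    variances, var = S10/m + S01/n.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both cases and controls required")
    gt = (x[:, None] > y[None, :]).astype(float)
    eq = (x[:, None] == y[None, :]).astype(float)
    psi = gt + 0.5 * eq
    auc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


@dataclass
class StratifiedAUC:
    """Bracket-averaged AUC with DeLong-combined uncertainty."""

    mean: float
    variance: float
    ci_low: float
    ci_high: float
    brackets: pd.DataFrame
    valid: bool = True


def combine_delong(bracket_means, bracket_variances) -> tuple[float, float, tuple]:
    """Unweighted mean of bracket AUCs; sigma^2 = (1/n^2) sum sigma_i^2."""
    mu_i = np.asarray(bracket_means, dtype=float)
    var_i = np.asarray(bracket_variances, dtype=float)
    n = len(mu_i)
    if n == 0:
        raise ValueError("no brackets to combine")
    mu = mu_i.mean()
    var = var_i.sum() / n**2
    half = stats.norm.ppf(0.975) * np.sqrt(var)
    return float(mu), float(var), (float(mu - half), float(mu + half))


def stratified_auc(
    scores: np.ndarray,
    outcomes: np.ndarray,
    ages_years: np.ndarray,
    sexes: np.ndarray | None = None,
    bracket_years: float = 5.0,
    age_range: tuple[float, float] = (50.0, 80.0),
    min_cases: int = 3,
) -> StratifiedAUC:
    """AUC within 5-year age (and sex) brackets, averaged across brackets.

    Brackets with fewer than ``min_cases`` cases (default: more than two
    required) or without both classes are skipped.  If no bracket
    qualifies the result is flagged invalid (mean NaN), never 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    ages_years = np.asarray(ages_years, dtype=float)
    sexes = (
        np.zeros(len(scores), dtype=object)
        if sexes is None
        else np.asarray(sexes, dtype=object)
    )
    edges = np.arange(age_range[0], age_range[1] + bracket_years, bracket_years)
    rows = []
    for sex in np.unique(sexes):
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (sexes == sex) & (ages_years >= lo) & (ages_years < hi)
            n_cases = int(outcomes[sel].sum())
            n_ctrl = int((~outcomes[sel]).sum())
            if n_cases < min_cases or n_ctrl == 0:
                continue
            auc, var = delong_auc_variance(
                scores[sel & outcomes], scores[sel & ~outcomes]
            )
            rows.append(
                {
                    "sex": sex,
                    "age_low": lo,
                    "age_high": hi,
                    "n_cases": n_cases,
                    "n_controls": n_ctrl,
                    "auc": auc,
                    "variance": var,
                }
            )
    brackets = pd.DataFrame(
        rows,
        columns=[
            "sex", "age_low", "age_high", "n_cases", "n_controls", "auc",
            "variance",
        ],
    )
    if brackets.empty:
        return StratifiedAUC(np.nan, np.nan, np.nan, np.nan, brackets, valid=False)
    mu, var, (lo, hi) = combine_delong(brackets["auc"], brackets["variance"])
    return StratifiedAUC(mu, var, lo, hi, brackets)


# ---------------------------------------------------------------------
# subgroup bias test
# ---------------------------------------------------------------------

@dataclass
class SubgroupVarianceResult:
    pooled_mean: float
    residuals: pd.DataFrame  # subgroup, mean, variance, residual, flagged
    chi2: float
    dof: int
    p_value: float
    flagged: bool


def subgroup_variance_test(
    subgroup_means,
    subgroup_variances,
    subgroup_labels=None,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> SubgroupVarianceResult:
    """Chi-square test for excess between-subgroup AUC variance.

    The pooled mean is precision-weighted; standardized residuals
    ``r_s = (mu_s - mu) / sigma_s`` are summed squared into a chi-square
    with ``n - 1`` degrees of freedom.  Residuals are flagged two-sided
    and the disease one-sided, both Bonferroni-corrected by
    ``n_comparisons``.
    """
    mu_s = np.asarray(subgroup_means, dtype=float)
    var_s = np.asarray(subgroup_variances, dtype=float)
    if len(mu_s) < 2:
        raise ValueError("at least two subgroups required")
    if np.any(var_s <= 0):
        raise ValueError("subgroup variances must be positive")
    labels = (
        [f"s{i}" for i in range(len(mu_s))]
        if subgroup_labels is None
        else list(subgroup_labels)
    )
    w = 1.0 / var_s
    mu = float((mu_s * w).sum() / w.sum())
    r = (mu_s - mu) / np.sqrt(var_s)
    chi2 = float((r**2).sum())
    dof = len(mu_s) - 1
    p = float(stats.chi2.sf(chi2, dof))
    z_crit = stats.norm.ppf(1 - alpha / (2 * n_comparisons))
    residuals = pd.DataFrame(
        {
            "subgroup": labels,
            "mean": mu_s,
            "variance": var_s,
            "residual": r,
            "flagged": np.abs(r) > z_crit,
        }
    )
    return SubgroupVarianceResult(
        pooled_mean=mu,
        residuals=residuals,
        chi2=chi2,
        dof=dof,
        p_value=p,
        flagged=p < alpha / n_comparisons,
    )


# ---------------------------------------------------------------------
# incidence cross-entropy, Nelson-Aalen
# ---------------------------------------------------------------------

def incidence_cross_entropy(p, q) -> float:
    """Sum of H(p, q) = -p log q - (1-p) log(1-q) over aligned cells.

    ``q`` must lie in (0, 1) wherever the corresponding ``p`` makes the
    term finite; a conflicting boundary value surfaces as ``inf``.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(p > 0, -p * np.log(q), 0.0)
        t2 = np.where(p < 1, -(1 - p) * np.log1p(-q), 0.0)
    return float((t1 + t2).sum())


def nelson_aalen_cumhaz(
    event_times: np.ndarray, censor_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nelson-Aalen cumulative hazard, sum of d_i/n_i at event times.

    Returns ``(times, cumhaz)`` step-function knots (right-continuous;
    value 0 before the first event).  Computed via lifelines.
    """
    from lifelines import NelsonAalenFitter

    event_times = np.asarray(event_times, dtype=float)
    censor_times = np.asarray(censor_times, dtype=float)
    durations = np.concatenate([event_times, censor_times])
    observed = np.concatenate(
        [np.ones(len(event_times)), np.zeros(len(censor_times))]
    )
    if len(durations) == 0:
        raise ValueError("no subjects at risk")
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(durations, event_observed=observed)
    series = naf.cumulative_hazard_.iloc[:, 0]
    return series.index.to_numpy(dtype=float), series.to_numpy(dtype=float)


# ---------------------------------------------------------------------
# person-time probe states and rate recovery
# ---------------------------------------------------------------------

def probe_state(traj: Trajectory, vocab: TokenVocabulary, age_days: float) -> Trajectory:
    """History before ``age_days`` with a no-event probe appended at it.

    Inserting a no-event token at an arbitrary age is the inference-time
    device for reading off predicted risks at any time of interest.
    """
    keep = traj.ages < age_days
    return Trajectory(
        traj.person_id,
        np.append(traj.ages[keep], age_days),
        np.append(traj.tokens[keep], vocab.no_event_index),
        traj.window_start,
        max(traj.window_end, age_days + 1.0),
    )


def sample_person_time_states(
    cohort: list[Trajectory],
    vocab: TokenVocabulary,
    n_states: int,
    age_range_years: tuple[float, float] = (30.0, 85.0),
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Random (person index, probe age in days) states.

    Persons must be alive, under observation and past their first event
    at the drawn age; draws failing that are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[int, float]] = []
    lo, hi = (a * DAYS_PER_YEAR for a in age_range_years)
    attempts = 0
    while len(out) < n_states and attempts < 100 * n_states:
        attempts += 1
        i = int(rng.integers(len(cohort)))
        traj = cohort[i]
        u = rng.uniform(lo, min(hi, traj.window_end))
        death = traj.death_age(vocab)
        if death is not None and death <= u:
            continue
        if not np.any(traj.ages < u):
            continue
        out.append((i, float(u)))
    return out


def rate_recovery_report(
    model,
    oracle,
    cohort: list[Trajectory],
    n_states: int = 2000,
    seed: int = 0,
    age_range_years: tuple[float, float] = (30.0, 85.0),
) -> pd.DataFrame:
    """Model vs ground-truth rates over sampled person-time states.

    For every sampled state and every still-possible predictable token
    (occurred diseases and the probe's own no-event token excluded),
    records the model's and the oracle's annual risk plus the observed
    one-year outcome.  The long-format frame feeds rank-correlation and
    calibration summaries.
    """
    vocab = model.vocab
    states = sample_person_time_states(
        cohort, vocab, n_states, age_range_years, seed
    )
    rows = []
    for i, u in states:
        traj = cohort[i]
        probe = probe_state(traj, vocab, u)
        model_rates = model.rate_vector(probe)
        oracle_rates_v = oracle.rate_vector(probe)
        occurred = {
            int(t)
            for t in probe.tokens
            if vocab.token_class(int(t)) == "disease"
        }
        for tok in np.flatnonzero(vocab.predictable_mask):
            tok = int(tok)
            if tok in occurred or tok == vocab.no_event_index:
                continue
            in_year = np.any(
                (traj.tokens == tok)
                & (traj.ages > u)
                & (traj.ages <= u + DAYS_PER_ANNUM)
            )
            rows.append(
                {
                    "person": traj.person_id,
                    "age_days": u,
                    "token": tok,
                    "model_rate": float(model_rates[tok]),
                    "oracle_rate": float(oracle_rates_v[tok]),
                    "model_annual": annual_risk_from_rate(model_rates[tok]),
                    "oracle_annual": annual_risk_from_rate(oracle_rates_v[tok]),
                    "outcome": bool(in_year),
                }
            )
    return pd.DataFrame(rows)


def calibration_slope(
    predicted_annual: np.ndarray,
    outcomes: np.ndarray,
    min_bin_n: int = 50,
) -> tuple[float, pd.DataFrame]:
    """Log-log slope of observed vs predicted annual risk across bins.

    Each datapoint is one person-year check; predictions are grouped in
    the geometric risk bins and the slope fitted by least squares on
    log10 of the occupied bin means (bins with cases only).  A
    well-calibrated predictor has slope 1.
    """
    curve = calibration_curve(predicted_annual, outcomes, band_years=1.0)
    occ = curve[(curve["n"] >= min_bin_n) & (curve["n_cases"] > 0)]
    if len(occ) < 2:
        return np.nan, curve
    x = np.log10(occ["predicted_mean"].to_numpy())
    y = np.log10(occ["observed_annual"].to_numpy())
    slope = float(np.polyfit(x, y, 1)[0])
    return slope, curve


def waiting_time_consistency(
    cohort: list[Trajectory],
    model,
    max_pairs: int = 2000,
    n_bins: int = 10,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Observed vs expected next-event times, binned regression slope.

    For each prediction source the expected waiting time is
    ``1 / sum(rates)``; the observed one is the actual gap to the next
    event.  Pairs are binned by expected time (log-spaced) and mean
    observed regressed on mean expected; a consistent rate model has
    slope 1.
    """
    from .loss import pair_targets

    vocab = model.vocab
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    exp_t, obs_t = [], []
    for i in order:
        traj = cohort[int(i)]
        pairing = pair_targets(traj.ages, traj.tokens, vocab)
        if len(pairing) == 0:
            continue
        # one forward pass per trajectory, reused across its pairs
        logits = model.logits(traj.tokens, traj.ages)[0]
        rates = np.exp(logits.astype(np.float64))
        rates[:, ~vocab.predictable_mask] = 0.0
        total = rates.sum(axis=1)
        seen_src = set()
        for s, w in zip(pairing.source_pos, pairing.waiting_days):
            if s in seen_src:  # co-occurring targets share one gap
                continue
            seen_src.add(s)
            if total[s] > 0:
                exp_t.append(1.0 / total[s])
                obs_t.append(float(w))
        if len(exp_t) >= max_pairs:
            break
    exp_arr, obs_arr = np.asarray(exp_t), np.asarray(obs_t)
    edges = np.geomspace(exp_arr.min(), exp_arr.max() * 1.0001, n_bins + 1)
    which = np.digitize(exp_arr, edges) - 1
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() < 10:
            continue
        rows.append(
            {
                "expected_mean": float(exp_arr[sel].mean()),
                "observed_mean": float(obs_arr[sel].mean()),
                "n": int(sel.sum()),
            }
        )
    binned = pd.DataFrame(rows)
    if len(binned) < 2:
        return np.nan, binned
    slope = float(
        np.polyfit(binned["expected_mean"], binned["observed_mean"], 1)[0]
    )
    return slope, binned


# ---------------------------------------------------------------------
# longitudinal harness
# ---------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-token longitudinal metrics plus cohort metadata."""

    per_token: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    empty: bool = False

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "metadata": self.metadata,
                "empty": self.empty,
                "per_token": self.per_token.to_dict(orient="records"),
            },
            indent=1,
            default=float,
        )

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_token.to_csv(directory / "per_token.tsv", sep="\t", index=False)
        (directory / "summary.json").write_text(self.to_json())


def longitudinal_eval(
    cohort: list[Trajectory],
    model,
    cutoff_age_years: float,
    gap_years: float = 1.0,
    horizon_years: float = 1.0,
    min_cases: int = 25,
    tokens: list[int] | None = None,
) -> EvalReport:
    """Truncate-at-cutoff forecasting harness.

    Histories are cut at ``cutoff_age_years``; predictions (annual risks
    from the last pre-cutoff state) are scored against outcomes accruing
    in the window ``(cutoff + gap, cutoff + gap + horizon]``.  Persons
    dead or out of observation before the window closes contribute no
    outcome (death itself stays a scorable outcome).  Tokens with fewer
    than ``min_cases`` cases are excluded.
    """
    vocab = model.vocab
    cutoff = cutoff_age_years * DAYS_PER_YEAR
    win_lo = cutoff + gap_years * DAYS_PER_YEAR
    win_hi = win_lo + horizon_years * DAYS_PER_YEAR
    female, male = vocab.sex_indices

    preds, rows_meta = [], []
    for traj in cohort:
        keep = traj.ages <= cutoff
        if not keep.any():
            continue
        death = traj.death_age(vocab)
        if death is not None and death <= cutoff:
            continue  # dead before prediction time
        if traj.window_end < win_hi and (death is None or death > win_hi):
            continue  # observation ends inside the window without death
        prefix = Trajectory(
            traj.person_id, traj.ages[keep], traj.tokens[keep],
            traj.window_start, traj.window_end,
        )
        rates = model.rate_vector(prefix)
        preds.append(annual_risk_from_rate(rates))
        in_window = (traj.ages > win_lo) & (traj.ages <= win_hi)
        rows_meta.append(
            {
                "person_id": traj.person_id,
                "sex": "male" if traj.sex_token(vocab) == male else "female",
                "tokens_in_window": set(traj.tokens[in_window].tolist()),
                "tokens_before_window": set(
                    traj.tokens[traj.ages <= win_lo].tolist()
                ),
                "died_before_window": death is not None and death <= win_lo,
            }
        )
    if not preds:
        return EvalReport(
            pd.DataFrame(), {"cutoff_age_years": cutoff_age_years}, empty=True
        )
    pred = np.asarray(preds)
    if tokens is None:
        tokens = [
            i for i in range(len(vocab)) if vocab.predictable_mask[i]
            and i != vocab.no_event_index
        ]
    rows = []
    for tok in tokens:
        outcome = np.array(
            [tok in m["tokens_in_window"] for m in rows_meta], dtype=bool
        )
        # first-occurrence semantics: anyone already carrying the token
        # (incl. death during the gap) cannot be a case in the window
        at_risk = np.array(
            [
                not m["died_before_window"]
                and tok not in m["tokens_before_window"]
                for m in rows_meta
            ],
            dtype=bool,
        )
        y = outcome[at_risk]
        s = pred[at_risk, tok]
        if int(y.sum()) < min_cases or y.all() or not y.any():
            continue
        rows.append(
            {
                "token": tok,
                "code": vocab.code(tok),
                "n": int(at_risk.sum()),
                "n_cases": int(y.sum()),
                "auc": float(roc_auc_score(y, s)),
                "average_precision": float(average_precision_score(y, s)),
                "mean_predicted": float(s.mean()),
                "observed_rate": float(y.mean() / horizon_years),
            }
        )
    per_token = pd.DataFrame(
        rows,
        columns=[
            "token", "code", "n", "n_cases", "auc", "average_precision",
            "mean_predicted", "observed_rate",
        ],
    )
    meta = {
        "cutoff_age_years": cutoff_age_years,
        "gap_years": gap_years,
        "horizon_years": horizon_years,
        "n_individuals": len(rows_meta),
        "min_cases": min_cases,
    }
    return EvalReport(per_token, meta, empty=per_token.empty)
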