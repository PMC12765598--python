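"""Time-stratified case-crossover analysis of recent predator exposure.

Every hourly herbivore detection (the *case*) is matched with up to five
*control* hours from the same camera cluster, calendar month and hour of
day during which the site was operational but the herbivore was not
detected. Exposure is the time since the last predator detection at that
cluster, categorised as short-term (0-6 h) or delayed (6-24 h); >= 24 h or
never is the reference. Because case and controls share site, season and
time of day, stratum-constant confounders cancel out of the conditional
likelihood and the exponentiated coefficients are odds ratios for herbivore
detection following recent predator presence.

The conditional logistic fit is authored here: Newton-Raphson with
step-halving on the exact conditional likelihood

    L(beta) = prod_s exp(x_case . beta) / sum_{j in s} exp(x_j . beta),

standard errors from the inverse observed information, with explicit
detection of separation (the infinite-MLE pathology that matched designs
with sparse exposure are prone to).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from datetime import datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from fearscape.data_model import DetectionEvent
from fearscape.event_prep import CameraCluster, _camera_to_cluster

__all__ = [
    "HourlyMatrix",
    "ExposureStatus",
    "Stratum",
    "CLogitFit",
    "build_hourly_matrix",
    "time_since_last",
    "build_strata",
    "fit_clogit",
    "lr_test",
    "concordance",
]

SHORT_MAX = 6.0
DELAYED_MAX = 24.0


@dataclass(frozen=True)
class ExposureStatus:
    """Lag to the most recent predator detection and its window category."""

    hours_since: float | None
    window: str  # "short" | "delayed" | "reference"


@dataclass
class HourlyMatrix:
    """Binary per-species detection indicators on the (cluster, hour) grid.

    ``data`` is indexed by (cluster_id, hour) with one 0/1 column per species
    plus ``operational``; ``first_times`` maps (cluster_id, hour, species) to
    the earliest raw timestamp within that hour, used to order same-hour
    co-detections.
    """

    data: pd.DataFrame
    species: tuple[str, ...]
    first_times: dict[tuple[str, pd.Timestamp, str], datetime] = field(
        default_factory=dict
    )


def build_hourly_matrix(
    events_filtered: Sequence[DetectionEvent],
    clusters: Sequence[CameraCluster],
    operational: Mapping[str, Sequence] | None = None,
    species: Sequence[str] | None = None,
) -> HourlyMatrix:
    """Floor detections to the hour and lay them on an operational hour grid.

    ``operational`` maps cluster_id to the iterable of operational calendar
    dates; when omitted it is inferred as the span from first to last
    detection at each cluster. Cluster-days are anchored at noon (a
    ``cluster_day`` column records the 12:00-11:59 day each hour belongs
    to), so a night's activity is not split across two days. Detections in
    non-operational hours are dropped with a warning.
    """
    cam2clu = _camera_to_cluster(clusters)
    if species is None:
        species = tuple(sorted({e.species for e in events_filtered}))
    else:
        species = tuple(species)

    ev = pd.DataFrame(
        [
            {
                "cluster_id": cam2clu[e.camera_id],
                "hour": pd.Timestamp(e.timestamp).floor("h"),
                "species": e.species,
                "ts": e.timestamp,
            }
            for e in events_filtered
            if e.species in species
        ]
    )

    frames = []
    if operational is not None:
        for cid, dates in operational.items():
            days = pd.to_datetime(sorted(set(pd.Timestamp(d) for d in dates)))
            hours = pd.DatetimeIndex(
                np.concatenate([pd.date_range(d, periods=24, freq="h").values
                                for d in days])
            ) if len(days) else pd.DatetimeIndex([])
            frames.append(pd.DataFrame({"cluster_id": cid, "hour": hours}))
    else:
        if ev.empty:
            raise ValueError("no events and no operational calendar supplied")
        for cid, grp in ev.groupby("cluster_id"):
            hours = pd.date_range(grp["hour"].min().normalize(),
                                  grp["hour"].max().normalize()
                                  + pd.Timedelta(hours=23), freq="h")
            frames.append(pd.DataFrame({"cluster_id": cid, "hour": hours}))
    grid = pd.concat(frames, ignore_index=True)
    grid["operational"] = 1

    mat = grid.set_index(["cluster_id", "hour"]).sort_index()
    for sp in species:
        mat[sp] = 0

    first_times: dict[tuple[str, pd.Timestamp, str], datetime] = {}
    n_dropped = 0
    if not ev.empty:
        for row in ev.itertuples(index=False):
            key = (row.cluster_id, row.hour)
            if key not in mat.index:
                n_dropped += 1
                continue
            mat.loc[key, row.species] = 1
            fkey = (row.cluster_id, row.hour, row.species)
            if fkey not in first_times or row.ts < first_times[fkey]:
                first_times[fkey] = row.ts
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} detection(s) in non-operational hours")

    hours_idx = mat.index.get_level_values("hour")
    mat["cluster_day"] = (hours_idx - pd.Timedelta(hours=12)).date
    return HourlyMatrix(mat, species, first_times)


def time_since_last(
    matrix: HourlyMatrix,
    predator: str,
    cluster_id: str,
    hour: pd.Timestamp,
    before_time: datetime | None = None,
) -> ExposureStatus:
    """Hours since the most recent predator detection at a cluster.

    Only predator hours strictly before ``hour`` count, except that a
    same-hour predator detection counts at lag 0 when ``before_time`` is
    given and the predator's earliest raw timestamp precedes it (the raw
    herbivore detection time) — this avoids counting reverse-order
    co-detections as exposure.
    """
    hour = pd.Timestamp(hour)
    try:
        sub = matrix.data.xs(cluster_id, level="cluster_id")
    except KeyError:
        return ExposureStatus(None, "reference")
    if predator not in sub.columns:
        return ExposureStatus(None, "reference")
    if before_time is not None and (cluster_id, hour, predator) in matrix.first_times:
        if matrix.first_times[(cluster_id, hour, predator)] < before_time:
            return ExposureStatus(0.0, "short")
    pred_hours = sub.index[(sub[predator] == 1) & (sub.index < hour)]
    if len(pred_hours) == 0:
        return ExposureStatus(None, "reference")
    lag = (hour - pred_hours.max()) / pd.Timedelta(hours=1)
    if lag < SHORT_MAX:
        return ExposureStatus(float(lag), "short")
    if lag < DELAYED_MAX:
        return ExposureStatus(float(lag), "delayed")
    return ExposureStatus(float(lag), "reference")


@dataclass(frozen=True)
class Stratum:
    """One case hour and its matched controls with exposure design rows.

    ``X`` has the case as row 0 and one row per control; columns follow
    ``indicator_names`` (predator x window dummies).
    """

    stratum_id: str
    cluster_id: str
    case_hour: pd.Timestamp
    control_hours: tuple[pd.Timestamp, ...]
    X: np.ndarray
    indicator_names: tuple[str, ...]


def _stratum_rng(seed: int, stratum_key: str) -> np.random.Generator:
    # counter-based: reproducible independent of stratum iteration order
    return np.random.default_rng([seed, zlib.crc32(stratum_key.encode())])


def exposure_vector(
    matrix: HourlyMatrix,
    predators: Sequence[str],
    cluster_id: str,
    hour: pd.Timestamp,
    before_time: datetime | None = None,
) -> np.ndarray:
    out = np.zeros(2 * len(predators))
    for i, pred in enumerate(predators):
        st = time_since_last(matrix, pred, cluster_id, hour, before_time)
        if st.window == "short":
            out[2 * i] = 1.0
        elif st.window == "delayed":
            out[2 * i + 1] = 1.0
    return out


def build_strata(
    matrix: HourlyMatrix,
    focal_species: str,
    predators: Sequence[str],
    k_controls: int = 5,
    seed: int = 0,
    same_hour_rule: bool = False,
) -> tuple[list[Stratum], int]:
    """Match each focal detection hour with up to ``k_controls`` control hours.

    Controls are drawn without replacement from operational hours at the
    same cluster, same calendar month and same hour of day with no focal
    detection; sampling is keyed by (seed, stratum id) so each stratum is
    reproducible in isolation. Returns the strata and the number of cases
    dropped for lack of any eligible control.

    By default same-hour predator co-detections are ignored for cases and
    controls alike, keeping the exposure definition symmetric — the
    defining property of the time-stratified referent. ``same_hour_rule``
    enables the alternative of counting a same-hour predator at lag 0 for a
    case when its raw timestamp precedes the herbivore's; because controls
    have no raw detection time this asymmetry inflates odds ratios when
    predators and prey co-occur by chance, so it is off by default.
    """
    names = tuple(
        f"{p}_{w}" for p in predators for w in ("short", "delayed")
    )
    df = matrix.data
    hour_ns = pd.Timedelta(hours=1).value
    strata: list[Stratum] = []
    n_dropped = 0

    for cluster_id, sub in df.groupby(level="cluster_id", sort=True):
        sub = sub.droplevel("cluster_id")
        hrs = sub.index
        # sorted predator detection hours (ns since epoch) for lag lookups;
        # a predator never seen in the data simply has no exposure hours
        pred_ns = {
            p: (np.sort(hrs[sub[p] == 1].asi8) if p in sub.columns
                else np.array([], dtype=np.int64))
            for p in predators
        }

        def expo(hour: pd.Timestamp, case_ts: datetime | None) -> np.ndarray:
            out = np.zeros(2 * len(predators))
            h_ns = hour.value
            for i, p in enumerate(predators):
                arr = pred_ns[p]
                lag = None
                if case_ts is not None:
                    ft = matrix.first_times.get((cluster_id, hour, p))
                    if ft is not None and ft < case_ts:
                        lag = 0.0
                if lag is None:
                    idx = np.searchsorted(arr, h_ns, side="left") - 1
                    if idx >= 0:
                        lag = (h_ns - arr[idx]) / hour_ns
                if lag is None:
                    continue
                if lag < SHORT_MAX:
                    out[2 * i] = 1.0
                elif lag < DELAYED_MAX:
                    out[2 * i + 1] = 1.0
            return out

        eligible = ((sub[focal_species] == 0)
                    & (sub["operational"] == 1)).to_numpy()
        # control pools keyed by (year, month, hour-of-day)
        pool_key = pd.MultiIndex.from_arrays(
            [hrs.year, hrs.month, hrs.hour])
        pools: dict[tuple, pd.DatetimeIndex] = {}
        for key, grp_hours in pd.Series(
                hrs, index=pool_key)[eligible].groupby(level=[0, 1, 2]):
            pools[key] = pd.DatetimeIndex(grp_hours.values)
        for case_hour in hrs[sub[focal_species] == 1]:
            pool = pools.get(
                (case_hour.year, case_hour.month, case_hour.hour),
                pd.DatetimeIndex([]))
            if len(pool) == 0:
                n_dropped += 1
                continue
            sid = f"{focal_species}|{cluster_id}|{case_hour.isoformat()}"
            rng = _stratum_rng(seed, sid)
            k = min(k_controls, len(pool))
            chosen = pd.DatetimeIndex(
                sorted(rng.choice(pool.values, size=k, replace=False))
            )
            case_ts = (matrix.first_times.get(
                (cluster_id, case_hour, focal_species))
                if same_hour_rule else None)
            rows = [expo(case_hour, case_ts)]
            rows += [expo(h, None) for h in chosen]
            strata.append(
                Stratum(sid, cluster_id, case_hour, tuple(chosen),
                        np.asarray(rows), names)
            )
    return strata, n_dropped


@dataclass
class CLogitFit:
    """Conditional logistic fit: coefficients, ORs, diagnostics."""

    params: pd.DataFrame  # index: indicator; columns coef, se, or_, ci_low, ci_high, p
    loglik: float
    loglik_null: float
    n_events: int
    n_strata: int
    converged: bool
    separation: dict[str, bool]
    dropped_indicators: tuple[str, ...]
    indicator_names: tuple[str, ...]
    lr_chi2: float = np.nan
    lr_df: int = 0
    lr_p: float = np.nan
    concordance_: float = np.nan


def _cond_loglik(beta: np.ndarray, Xs: list[np.ndarray]) -> float:
    ll = 0.0
    for X in Xs:
        eta = X @ beta
        ll += eta[0] - logsumexp(eta)
    return ll


def _grad_hess(beta: np.ndarray, Xs: list[np.ndarray]):
    p = len(beta)
    g = np.zeros(p)
    H = np.zeros((p, p))
    for X in Xs:
        eta = X @ beta
        w = np.exp(eta - logsumexp(eta))
        xbar = w @ X
        g += X[0] - xbar
        H -= (X * w[:, None]).T @ X - np.outer(xbar, xbar)
    return g, H


def fit_clogit(
    strata: Sequence[Stratum],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CLogitFit:
    """Maximise the conditional likelihood by Newton-Raphson with step-halving.

    Indicators with no within-stratum variation carry no information under
    the conditional likelihood and are dropped with a warning. Separation
    (all exposed units on one side of the case/control divide) drives the
    MLE to infinity; it is flagged per coefficient when ``|beta| > 10`` or
    ``SE > 100`` and the coefficient reported as unstable rather than
    silently finite.
    """
    if not strata:
        raise ValueError("no strata to fit")
    names = strata[0].indicator_names
    Xs_all = [s.X for s in strata]

    # an indicator is estimable iff it varies within at least one stratum
    keep, dropped = [], []
    for j, name in enumerate(names):
        varies = any(len(np.unique(X[:, j])) > 1 for X in Xs_all)
        (keep if varies else dropped).append((j, name))
    if dropped:
        warnings.warn(
            "dropped indicator(s) without within-stratum variation: "
            + ", ".join(n for _, n in dropped)
        )
    keep_idx = [j for j, _ in keep]
    keep_names = tuple(n for _, n in keep)
    Xs = [X[:, keep_idx] for X in Xs_all]
    p = len(keep_idx)
    ll_null = float(sum(-np.log(X.shape[0]) for X in Xs_all))

    beta = np.zeros(p)
    ll = _cond_loglik(beta, Xs) if p else ll_null
    converged = p == 0
    for _ in range(max_iter):
        if p == 0:
            break
        g, H = _grad_hess(beta, Xs)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = -np.linalg.pinv(H) @ g
        # step-halving: insist on likelihood improvement
        t = 1.0
        for _ in range(30):
            new_beta = beta + t * step
            new_ll = _cond_loglik(new_beta, Xs)
            if new_ll >= ll - 1e-12:
                break
            t /= 2.0
        if not np.isfinite(new_ll):
            break
        improved = new_ll - ll
        beta, ll = new_beta, new_ll
        if abs(improved) < tol:
            converged = True
            break

    if p:
        _, H = _grad_hess(beta, Xs)
        try:
            cov = np.linalg.inv(-H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.inf)
    else:
        se = np.array([])

    rows = {}
    separation = {}
    for name in names:
        if name in keep_names:
            j = keep_names.index(name)
            b, s = float(beta[j]), float(se[j])
            sep = abs(b) > 10.0 or s > 100.0
            separation[name] = sep
            z = b / s if s > 0 else np.nan
            rows[name] = {
                "coef": b,
                "se": s,
                "or_": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.96 * s)),
                "ci_high": float(np.exp(b + 1.96 * s)),
                "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                "unstable": sep,
            }
        else:
            separation[name] = False
            rows[name] = {c: np.nan for c in
                          ("coef", "se", "or_", "ci_low", "ci_high", "p")}
            rows[name]["unstable"] = False

    fit = CLogitFit(
        params=pd.DataFrame.from_dict(rows, orient="index"),
        loglik=float(ll),
        loglik_null=ll_null,
        n_events=len(strata),
        n_strata=len(strata),
        converged=converged,
        separation=separation,
        dropped_indicators=tuple(n for _, n in dropped),
        indicator_names=names,
    )
    chi2, dof, pval = lr_test(fit, strata)
    fit.lr_chi2, fit.lr_df, fit.lr_p = chi2, dof, pval
    fit.concordance_ = concordance(fit, strata)
    return fit


def lr_test(fit: CLogitFit, strata: Sequence[Stratum]) -> tuple[float, int, float]:
    """Likelihood-ratio test of the fitted model against all-zero coefficients.

    The null conditional log-likelihood of a stratum of size m is -log(m).
    """
    ll_null = float(sum(-np.log(s.X.shape[0]) for s in strata))
    chi2 = max(0.0, 2.0 * (fit.loglik - ll_null))
    dof = len(fit.indicator_names) - len(fit.dropped_indicators)
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else np.nan
    return chi2, dof, p


def concordance(fit: CLogitFit, strata: Sequence[Stratum]) -> float:
    """Share of within-stratum (case, control) pairs ranked correctly.

    The case's fitted linear predictor beats the control's -> 1, ties 0.5.
    """
    names = fit.indicator_names
    beta = np.array(
        [fit.params.loc[n, "coef"] if np.isfinite(fit.params.loc[n, "coef"])
         else 0.0 for n in names]
    )
    num = 0.0
    den = 0
    for s in strata:
        eta = s.X @ beta
        case = eta[0]
        for ctrl in eta[1:]:
            den += 1
            if case > ctrl:
                num += 1.0
            elif case == ctrl:
                num += 0.5
    return num / den if den else np.nan


def results_table(fit: CLogitFit) -> pd.DataFrame:
    """Publication-style table: effect, coefficient, SE, OR, 95% CI, p."""
    df = fit.params.copy()
    df.index.name = "effect"
    df["ci"] = df.apply(
        lambda r: (f"{r.ci_low:.2f}-{r.ci_high:.2f}"
                   if np.isfinite(r.ci_low) and not r.unstable else "Inf"),
        axis=1,
    )
    return df[["coef", "se", "or_", "ci", "p"]]
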