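"""Maximum-likelihood spatial capture-recapture (SCR) for camera-trap surveys.

Density is estimated from spatially referenced photographic detections of
identified individuals.  Each animal is assumed to have a latent activity
center ``s`` distributed uniformly over a discretized "state space" built by
buffering the trap array; the probability of detecting it at a trap a distance
``d`` from ``s`` follows a half-normal encounter model

    p = p0 * exp(-d^2 / (2 sigma^2)),

with the baseline ``p0`` on a logit link and the spatial scale ``sigma`` on a
log link.  Covariates on ``p0`` may include survey session, sex, camera-site
location type and a trap-specific ("local") behavioral response that switches
on after an individual's first capture at that trap; ``sigma`` may depend on
sex.  The likelihood is conditional on detection, and abundance is recovered
with the Horvitz-Thompson estimator (sum of inverse detection probabilities),
so no data augmentation is required.  Multi-session data share one parameter
vector; models are compared by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp

LOCATION_TYPES = ("marking_site", "forest_road", "other")

__all__ = [
    "StateSpaceGrid",
    "SessionData",
    "CaptureDataset",
    "ScrModelSpec",
    "ScrFit",
    "build_state_space",
    "detection_prob",
    "negative_log_likelihood",
    "fit_scr",
    "aic_table",
    "seasonal_filter",
    "turnover",
]


@dataclass
class StateSpaceGrid:
    """Regular lattice of candidate activity-center locations."""

    centers: np.ndarray          # (n_cells, 2) meters
    cell: float                  # cell side, meters
    buffer: float                # buffer width used, meters

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def area_km2(self) -> float:
        return self.n_cells * (self.cell / 1000.0) ** 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.centers, columns=["x", "y"])


def build_state_space(
    traps: pd.DataFrame | np.ndarray,
    buffer: float = 15_000.0,
    cell: float = 2_500.0,
) -> StateSpaceGrid:
    """Lattice of cell centers covering the union of trap-centered buffer disks.

    The lattice is anchored at the minimum trap coordinate so the grid is
    deterministic for a given trap array; a cell is kept iff its center lies
    within ``buffer`` of at least one trap.
    """
    xy = traps[["x", "y"]].to_numpy(float) if isinstance(traps, pd.DataFrame) else np.asarray(traps, float)
    if xy.size == 0:
        raise ValueError("need at least one trap")
    if not np.isfinite(xy).all():
        raise ValueError("trap coordinates must be finite")
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    nx = np.arange(lo[0] - buffer, hi[0] + buffer + cell, cell)
    ny = np.arange(lo[1] - buffer, hi[1] + buffer + cell, cell)
    gx, gy = np.meshgrid(nx, ny, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((centers[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    keep = (d2 <= buffer**2).any(axis=1)
    return StateSpaceGrid(centers=centers[keep], cell=float(cell), buffer=float(buffer))


@dataclass
class SessionData:
    """One survey year: traps, identified individuals and their detections."""

    session: str
    traps: pd.DataFrame            # trap_id, x, y, location_type[, n_occasions_active]
    individuals: pd.DataFrame      # individual_id, sex
    n_occasions: int
    detections: np.ndarray         # (n_ind, n_traps, n_occasions) in {0,1}

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=np.int8)
        n_ind, n_traps, n_occ = self.detections.shape
        if n_ind != len(self.individuals) or n_traps != len(self.traps):
            raise ValueError("detections shape inconsistent with traps/individuals")
        if n_occ != self.n_occasions:
            raise ValueError("detections shape inconsistent with n_occasions")
        if n_ind and not (self.detections.sum(axis=(1, 2)) > 0).all():
            raise ValueError("every listed individual must have >=1 detection")
        if "location_type" in self.traps.columns:
            bad = set(self.traps["location_type"]) - set(LOCATION_TYPES)
            if bad:
                raise ValueError(f"unknown location types: {sorted(bad)}")


@dataclass
class CaptureDataset:
    """Ordered multi-session capture data."""

    sessions: list[SessionData]

    @property
    def session_names(self) -> list[str]:
        return [s.session for s in self.sessions]

    @property
    def n_detected(self) -> int:
        return sum(len(s.individuals) for s in self.sessions)


@dataclass(frozen=True)
class ScrModelSpec:
    """Which covariates enter baseline detection and the spatial scale.

    Reference categories: female, marking_site, first session, pre-response
    (naive) capture state.
    """

    p0_covariates: frozenset = frozenset()
    sigma_covariates: frozenset = frozenset()

    _P0_ALLOWED = frozenset({"session", "sex", "location_type", "behavior"})
    _SIG_ALLOWED = frozenset({"sex"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "p0_covariates", frozenset(self.p0_covariates))
        object.__setattr__(self, "sigma_covariates", frozenset(self.sigma_covariates))
        if not self.p0_covariates <= self._P0_ALLOWED:
            raise ValueError(f"p0 covariates must be in {sorted(self._P0_ALLOWED)}")
        if not self.sigma_covariates <= self._SIG_ALLOWED:
            raise ValueError("sigma covariates must be in {'sex'}")

    @classmethod
    def from_formula(cls, formula: str) -> "ScrModelSpec":
        """Parse e.g. ``"p0~session+sex+type+b, sigma~sex"``; ``~1`` = intercept-only."""
        alias = {"type": "location_type", "b": "behavior", "year": "session"}
        p0: set[str] = set()
        sig: set[str] = set()
        for part in formula.replace(" ", "").split(","):
            if not part:
                continue
            lhs, _, rhs = part.partition("~")
            terms = {alias.get(t, t) for t in rhs.split("+") if t and t != "1"}
            if lhs == "p0":
                p0 = terms
            elif lhs == "sigma":
                sig = terms
            else:
                raise ValueError(f"unknown model component {lhs!r}")
        return cls(frozenset(p0), frozenset(sig))

    def parameter_names(self, session_names: Sequence[str]) -> list[str]:
        names = ["p0_intercept"]
        if "session" in self.p0_covariates:
            names += [f"p0_session[{s}]" for s in session_names[1:]]
        if "sex" in self.p0_covariates:
            names += ["p0_sex[male]"]
        if "location_type" in self.p0_covariates:
            names += [f"p0_type[{t}]" for t in LOCATION_TYPES[1:]]
        if "behavior" in self.p0_covariates:
            names += ["p0_behavior[b]"]
        names += ["log_sigma"]
        if "sex" in self.sigma_covariates:
            names += ["log_sigma_sex[male]"]
        return names


def detection_prob(
    p0: float, sigma: float, distance: float | np.ndarray
) -> float | np.ndarray:
    """Half-normal encounter probability p0 * exp(-d^2 / (2 sigma^2))."""
    d = np.asarray(distance, float)
    if (d < 0).any():
        raise ValueError("distance must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = p0 * np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Likelihood machinery


def _unpack(theta: np.ndarray, spec: ScrModelSpec, session_names: Sequence[str]):
    names = spec.parameter_names(session_names)
    if len(theta) != len(names):
        raise ValueError(f"expected {len(names)} parameters, got {len(theta)}")
    return dict(zip(names, theta))


def _p0_logit(params: Mapping[str, float], spec: ScrModelSpec,
              session: str, session_names: Sequence[str],
              sex_male: int, trap_types: np.ndarray, behavior: int) -> np.ndarray:
    """Per-trap logit of p0 for one (session, sex, behavioral-state) stratum."""
    lp = np.full(len(trap_types), params["p0_intercept"])
    if "session" in spec.p0_covariates and session != session_names[0]:
        lp += params[f"p0_session[{session}]"]
    if "sex" in spec.p0_covariates and sex_male:
        lp += params["p0_sex[male]"]
    if "location_type" in spec.p0_covariates:
        for t in LOCATION_TYPES[1:]:
            lp += np.where(trap_types == t, params[f"p0_type[{t}]"], 0.0)
    if "behavior" in spec.p0_covariates and behavior:
        lp += params["p0_behavior[b]"]
    return lp


def _sigma(params: Mapping[str, float], spec: ScrModelSpec, sex_male: int) -> float:
    ls = params["log_sigma"]
    if "sex" in spec.sigma_covariates and sex_male:
        ls += params["log_sigma_sex[male]"]
    return float(np.exp(ls))


def _occ_counts(session: SessionData) -> np.ndarray:
    """Per-trap number of active occasions K_j."""
    if "n_occasions_active" in session.traps.columns:
        return session.traps["n_occasions_active"].to_numpy(int)
    return np.full(len(session.traps), session.n_occasions, dtype=int)


def _behavior_counts(y: np.ndarray, k_j: np.ndarray):
    """Collapse an individual's occasion-level history by behavioral state.

    For each trap, occasions up to and including the first capture there are
    in the naive state; later occasions are in the responded state.  Returns
    (y0, n0, y1, n1) per trap — capture and trial counts in each state.  The
    collapse is exact because detection probability is constant within state.
    """
    n_traps, n_occ = y.shape
    tot = y.sum(axis=1)
    caught = tot > 0
    first = np.where(caught, np.argmax(y > 0, axis=1), n_occ)
    n0 = np.where(caught, np.minimum(first + 1, k_j), k_j)
    y0 = caught.astype(int)
    n1 = k_j - n0
    y1 = tot - y0
    return y0, n0, y1, n1


def _session_nll_terms(
    params: Mapping[str, float],
    session: SessionData,
    grid: StateSpaceGrid,
    spec: ScrModelSpec,
    session_names: Sequence[str],
) -> float:
    xy = session.traps[["x", "y"]].to_numpy(float)
    d2 = ((grid.centers[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)  # cells x traps
    trap_types = (
        session.traps["location_type"].to_numpy()
        if "location_type" in session.traps.columns
        else np.full(len(session.traps), LOCATION_TYPES[0])
    )
    k_j = _occ_counts(session)
    use_b = "behavior" in spec.p0_covariates
    sexes = session.individuals["sex"].map({"male": 1}).fillna(0).astype(int).to_numpy()

    nll = 0.0
    log_ncells = np.log(grid.n_cells)
    for sex_male in np.unique(sexes):
        idx = np.flatnonzero(sexes == sex_male)
        sig = _sigma(params, spec, sex_male)
        kern = np.exp(-d2 / (2.0 * sig**2))
        p0_naive = expit(_p0_logit(params, spec, session.session, session_names,
                                   sex_male, trap_types, behavior=0))
        p_naive = np.clip(p0_naive[None, :] * kern, 1e-300, 1 - 1e-12)
        log_p = np.log(p_naive)
        log_q = np.log1p(-p_naive)
        # Pr(detected at least once | s), marginalized over cells (naive params);
        # cells far from every trap give pbar_s = 0 -> -inf, absorbed by logsumexp
        with np.errstate(divide="ignore"):
            log_pbar_s = np.log1p(-np.exp((log_q * k_j[None, :]).sum(axis=1)))
        log_pbar = logsumexp(log_pbar_s) - log_ncells

        y = session.detections[idx]  # (m, traps, occ)
        if use_b:
            p0_b = expit(_p0_logit(params, spec, session.session, session_names,
                                   sex_male, trap_types, behavior=1))
            p_b = np.clip(p0_b[None, :] * kern, 1e-300, 1 - 1e-12)
            log_pb = np.log(p_b)
            log_qb = np.log1p(-p_b)
            for yi in y:
                y0, n0, y1, n1 = _behavior_counts(yi, k_j)
                ll_s = (
                    log_p @ y0 + log_q @ (n0 - y0)
                    + log_pb @ y1 + log_qb @ (n1 - y1)
                )
                nll -= logsumexp(ll_s) - log_ncells - log_pbar
        else:
            y_jt = y.sum(axis=2)  # (m, traps)
            ll = y_jt @ log_p.T + (k_j[None, :] - y_jt) @ log_q.T  # (m, cells)
            nll -= (logsumexp(ll, axis=1) - log_ncells - log_pbar).sum()
    return nll


def negative_log_likelihood(
    theta: np.ndarray,
    data: CaptureDataset,
    grid: StateSpaceGrid,
    spec: ScrModelSpec,
) -> float:
    """Conditional-on-detection multi-session SCR negative log-likelihood.

    Each detected individual contributes
    ``-log( sum_s pi(s) Pr(history | s) / pbar )`` with ``pi`` uniform over the
    state-space cells and ``pbar`` the cell-marginal probability of being
    detected at all under naive (pre-response) parameters.
    """
    params = _unpack(np.asarray(theta, float), spec, data.session_names)
    nll = 0.0
    for session in data.sessions:
        if len(session.individuals) == 0:
            continue
        nll += _session_nll_terms(params, session, grid, spec, data.session_names)
    if not np.isfinite(nll):
        return 1e12
    return float(nll)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class ScrFit:
    """Fitted SCR model: estimates, uncertainty, abundance and density."""

    spec: ScrModelSpec
    params: pd.Series
    se: pd.Series
    loglik: float
    aic: float
    n_params: int
    abundance: pd.DataFrame        # session, sex, n_obs, N_hat, se, lcl, ucl
    density: pd.DataFrame          # session, D_hat (per 100 km^2), lcl, ucl
    converged: bool
    gradient_norm: float
    label: str = "scr"
    vcov: np.ndarray | None = None


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = np.zeros((k, k))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    del f0
    return h


def _pbar_by_stratum(
    params: Mapping[str, float],
    data: CaptureDataset,
    grid: StateSpaceGrid,
    spec: ScrModelSpec,
) -> dict[tuple[str, int], float]:
    """Cell-marginal detection probability per (session, sex) stratum."""
    out: dict[tuple[str, int], float] = {}
    for session in data.sessions:
        xy = session.traps[["x", "y"]].to_numpy(float)
        d2 = ((grid.centers[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        trap_types = (
            session.traps["location_type"].to_numpy()
            if "location_type" in session.traps.columns
            else np.full(len(session.traps), LOCATION_TYPES[0])
        )
        k_j = _occ_counts(session)
        for sex_male in (0, 1):
            sig = _sigma(params, spec, sex_male)
            p0 = expit(_p0_logit(params, spec, session.session, data.session_names,
                                 sex_male, trap_types, behavior=0))
            p = np.clip(p0[None, :] * np.exp(-d2 / (2 * sig**2)), 0.0, 1 - 1e-12)
            pbar_s = 1.0 - np.exp((np.log1p(-p) * k_j[None, :]).sum(axis=1))
            out[(session.session, sex_male)] = float(pbar_s.mean())
    return out


def _abundance_tables(theta, data, grid, spec, vcov, nll_fn):
    """Horvitz-Thompson abundance and density with log-scale delta-method CIs."""
    params = _unpack(theta, spec, data.session_names)
    pbar = _pbar_by_stratum(params, data, grid, spec)

    counts: dict[tuple[str, int], int] = {}
    for session in data.sessions:
        sexes = session.individuals["sex"].map({"male": 1}).fillna(0).astype(int)
        for sex_male in (0, 1):
            counts[(session.session, sex_male)] = int((sexes == sex_male).sum())

    def n_hat_vec(th) -> np.ndarray:
        pb = _pbar_by_stratum(_unpack(th, spec, data.session_names), data, grid, spec)
        return np.array([
            counts[k] / pb[k] if counts[k] else 0.0 for k in sorted(counts)
        ])

    keys = sorted(counts)
    n_hat = n_hat_vec(theta)
    # parameter-uncertainty component via numeric gradient of N_hat
    grads = np.zeros((len(keys), len(theta)))
    if vcov is not None:
        steps = 1e-4 * np.maximum(1.0, np.abs(theta))
        for j in range(len(theta)):
            ej = np.zeros(len(theta)); ej[j] = steps[j]
            grads[:, j] = (n_hat_vec(theta + ej) - n_hat_vec(theta - ej)) / (2 * steps[j])
    rows = []
    for i, (sess, sex_male) in enumerate(keys):
        n_obs = counts[(sess, sex_male)]
        pb = pbar[(sess, sex_male)]
        # Poisson (expected-abundance) variance: the estimand is the intensity
        # of the point process, not the realized N, so Var(n)/pbar^2 = n/pbar^2
        var_bin = n_obs / pb**2
        var_par = float(grads[i] @ vcov @ grads[i]) if vcov is not None else 0.0
        var = var_bin + var_par
        nh = n_hat[i]
        if nh > 0 and var > 0:
            cv2 = var / nh**2
            c = float(np.exp(1.959963984540054 * np.sqrt(np.log1p(cv2))))
            lcl, ucl = nh / c, nh * c
        else:
            lcl = ucl = nh
        rows.append({
            "session": sess, "sex": "male" if sex_male else "female",
            "n_obs": n_obs, "N_hat": nh, "se": np.sqrt(var), "lcl": lcl, "ucl": ucl,
        })
    ab = pd.DataFrame(rows)

    dens_rows = []
    for sess in data.session_names:
        sub = ab[ab["session"] == sess]
        nh = sub["N_hat"].sum()
        var = (sub["se"] ** 2).sum()
        d_hat = nh / grid.area_km2 * 100.0
        if nh > 0 and var > 0:
            cv2 = var / nh**2
            c = float(np.exp(1.959963984540054 * np.sqrt(np.log1p(cv2))))
            lcl, ucl = d_hat / c, d_hat * c
        else:
            lcl = ucl = d_hat
        dens_rows.append({
            "session": sess, "N_hat": nh, "D_hat": d_hat, "lcl": lcl, "ucl": ucl,
        })
    return ab, pd.DataFrame(dens_rows)


def _median_intertrap(data: CaptureDataset) -> float:
    xy = np.vstack([s.traps[["x", "y"]].to_numpy(float) for s in data.sessions])
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    vals = d[np.triu_indices(len(xy), k=1)]
    vals = vals[vals > 0]
    return float(np.median(vals)) if vals.size else 1000.0


def fit_scr(
    data: CaptureDataset,
    grid: StateSpaceGrid,
    spec: ScrModelSpec | str = ScrModelSpec(),
    start: np.ndarray | None = None,
    gtol: float = 1e-5,
    label: str | None = None,
    compute_vcov: bool = True,
) -> ScrFit:
    """Maximize the conditional SCR likelihood and derive abundance/density.

    Start values: logit p0 = -2, log sigma = log(half the median inter-trap
    distance), all covariate coefficients 0.  Standard errors come from the
    numeric Hessian; a singular Hessian yields missing SEs rather than failure.
    """
    if isinstance(spec, str):
        spec = ScrModelSpec.from_formula(spec)
    if data.n_detected < 2:
        raise ValueError("need at least 2 detected individuals")
    names = spec.parameter_names(data.session_names)
    if start is None:
        start = np.zeros(len(names))
        start[names.index("p0_intercept")] = -2.0
        start[names.index("log_sigma")] = np.log(_median_intertrap(data) / 2.0)

    nll = lambda th: negative_log_likelihood(th, data, grid, spec)  # noqa: E731
    res = optimize.minimize(nll, start, method="L-BFGS-B",
                            options={"gtol": gtol, "maxiter": 500})
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    theta = res.x

    vcov = None
    se = np.full(len(theta), np.nan)
    if compute_vcov:
        hess = _numeric_hessian(nll, theta)
        try:
            vcov = np.linalg.inv(hess)
            diag = np.diag(vcov)
            if (diag > 0).all():
                se = np.sqrt(diag)
            else:
                vcov = None
        except np.linalg.LinAlgError:
            vcov = None

    ab, dens = _abundance_tables(theta, data, grid, spec, vcov, nll)
    loglik = -float(res.fun)
    k = len(theta)
    return ScrFit(
        spec=spec,
        params=pd.Series(theta, index=names),
        se=pd.Series(se, index=names),
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_params=k,
        abundance=ab,
        density=dens,
        converged=bool(res.success),
        gradient_norm=gnorm,
        label=label or "+".join(sorted(spec.p0_covariates)) or "p0~1",
        vcov=vcov,
    )


def aic_table(fits: Iterable[ScrFit]) -> pd.DataFrame:
    """Rank fitted models by AIC with delta-AIC and Akaike weights."""
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    df = pd.DataFrame({
        "model": [f.label for f in fits],
        "k": [f.n_params for f in fits],
        "logLik": [f.loglik for f in fits],
        "AIC": [f.aic for f in fits],
    })
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    w = np.exp(-df["dAIC"] / 2.0)
    df["weight"] = w / w.sum()
    return df.sort_values("AIC", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Survey bookkeeping


def seasonal_filter(
    records: pd.DataFrame,
    date_column: str = "date",
    start: tuple[int, int] = (8, 15),
    end: tuple[int, int] = (2, 15),
) -> pd.DataFrame:
    """Restrict detection records to the demographic-closure season.

    Keeps rows whose date falls in the cross-year window [Aug 15, Feb 15]
    (inclusive) and assigns the survey ``session`` as the calendar year of the
    window's August boundary, so a January detection belongs to the previous
    year's session.  Idempotent.
    """
    dates = pd.to_datetime(records[date_column])
    md = dates.dt.month * 100 + dates.dt.day
    s = start[0] * 100 + start[1]
    e = end[0] * 100 + end[1]
    keep = (md >= s) | (md <= e)
    out = records.loc[keep].copy()
    kept_dates = dates.loc[keep]
    out["session"] = np.where(
        (kept_dates.dt.month * 100 + kept_dates.dt.day) >= s,
        kept_dates.dt.year,
        kept_dates.dt.year - 1,
    )
    return out.reset_index(drop=True)


def turnover(yearly_sets: Mapping[int | str, Iterable[str]]) -> pd.Series:
    """Per-year proportion of identified individuals redetected the next year."""
    keys = sorted(yearly_sets)
    if len(keys) < 2:
        raise ValueError("need at least two consecutive years")
    out = {}
    for a, b in zip(keys[:-1], keys[1:]):
        sa, sb = set(yearly_sets[a]), set(yearly_sets[b])
        out[a] = len(sa & sb) / len(sa) if sa else np.nan
    return pd.Series(out, name="turnover")
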