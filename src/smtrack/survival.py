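"""Residence-time analysis via survival distributions.

The chain implemented here is the standard single-molecule dwell-time
workflow for nuclear factors:

1. :func:`classify_bound` — call bound segments on tracks (a molecule is
   "bound" while it stays within ``r_max`` of a local centroid for at
   least ``n_min`` consecutive frames);
2. :func:`build_survival` — count dwell times into a survival curve
   S(t) = fraction of bound molecules still bound at dwell >= t,
   normalized to the bound fraction C_eq = (bound detections) / (all
   detections in all movie frames);
3. :func:`correct_photobleaching` — remove the fluorophore-death
   component by one of three methods (intrinsic, whole-reference,
   immobile-fraction of a stable reference such as histone H3);
4. :func:`fit_dwell_models` — fit exponential mixtures (1-3 components),
   a power law, and a power-law + exponential hybrid, and select by BIC;
5. :func:`derive_kinetics` — turn a bi-exponential fit into binding
   kinetics: residence times, search time, N_trials, and on-rates.

Photobleaching is counted per *exposure* (cumulative exposure count),
not per wall-clock second, so time-lapse regimes with dark intervals are
corrected consistently; conversion to seconds happens only at reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .trackio import TrackSet

__all__ = [
    "BoundSegment",
    "SurvivalCurve",
    "DwellModelFit",
    "BindingKinetics",
    "classify_bound",
    "build_survival",
    "correct_photobleaching",
    "fit_dwell_models",
    "derive_kinetics",
]

#: Model families fitted by :func:`fit_dwell_models`.
FAMILIES = ("exp_1", "exp_2", "exp_3", "power_law", "power_plus_exp")


@dataclass(frozen=True)
class BoundSegment:
    """One maximal run of consecutive frames a molecule stayed put."""

    track_id: int
    start_frame: int
    end_frame: int
    dwell: float  # seconds, (run length - 1) * frame interval
    censored_at_movie_end: bool = False

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")
        if not (self.dwell > 0):
            raise ValueError("dwell must be > 0")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class SurvivalCurve:
    """Fraction of bound molecules still observed bound vs dwell time.

    ``S`` is scaled so the first grid point equals the bound fraction
    ``C_eq`` when ``normalization == "bound_fraction"``.  ``counts`` holds
    the number of segments surviving at each grid point and drives the
    inverse-variance weights used in fitting.  ``correction`` records the
    photobleaching correction provenance.
    """

    times: np.ndarray
    S: np.ndarray
    counts: np.ndarray
    n0: int
    C_eq: float
    frame_interval: float
    normalization: str = "bound_fraction"
    correction: str = "none"
    detections_per_frame: np.ndarray | None = None
    bleach_factor: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if not (0.0 <= self.C_eq <= 1.0):
            raise ValueError(f"C_eq must be in [0, 1], got {self.C_eq}")

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "S": self.S.tolist(),
            "counts": self.counts.tolist(),
            "n0": self.n0,
            "C_eq": self.C_eq,
            "frame_interval": self.frame_interval,
            "normalization": self.normalization,
            "correction": self.correction,
            "provenance": self.provenance,
        }


@dataclass
class DwellModelFit:
    """One fitted dwell-time model and its BIC score.

    ``params`` holds the family's native parameters; for exponential
    mixtures ``fractions``/``taus`` are sorted fast-to-slow dissociation
    (ascending tau) and fractions sum to 1 over the bound population.
    """

    family: str
    params: dict
    fractions: tuple[float, ...]
    taus: tuple[float, ...]
    bic: float
    n_points: int
    rss_weighted: float
    success: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.params,
            "fractions": list(self.fractions),
            "taus": list(self.taus),
            "bic": self.bic,
            "n_points": self.n_points,
            "rss_weighted": self.rss_weighted,
            "success": self.success,
            "message": self.message,
        }


@dataclass(frozen=True)
class BindingKinetics:
    """Binding kinetics derived from a bi-exponential dwell fit.

    The short residence time is interpreted as non-specific binding
    (searching) and the long one as specific binding; ``tau_res`` is the
    fraction-weighted mean residence time, ``tau_search`` the average time
    spent diffusing between specific binding events, ``n_trials`` the
    expected number of sites sampled before a specific motif is found,
    and ``k_on_star = 1/tau_search`` the pseudo on-rate.  A true ``k_on``
    is reported only when the accessible-motif fraction ``S_eq`` is given.
    """

    C_eq: float
    F_NS: float
    F_S: float
    tau_NS: float
    tau_S: float
    tau_res: float
    tau_search: float
    n_trials: float
    k_on_star: float
    k_off_NS: float
    k_off_S: float
    S_eq: float | None = None
    k_on: float | None = None

    def to_dict(self) -> dict:
        d = {
            "C_eq": self.C_eq,
            "F_NS": self.F_NS,
            "F_S": self.F_S,
            "tau_NS": self.tau_NS,
            "tau_S": self.tau_S,
            "tau_res": self.tau_res,
            "tau_search": self.tau_search,
            "n_trials": self.n_trials,
            "k_on_star": self.k_on_star,
            "k_off_NS": self.k_off_NS,
            "k_off_S": self.k_off_S,
        }
        if self.S_eq is not None:
            d["S_eq"] = self.S_eq
            d["k_on"] = self.k_on
        return d


# ---------------------------------------------------------------------------
# bound-segment classification


def classify_bound(ts: TrackSet, r_max: float = 0.22, n_min: int = 3) -> list[BoundSegment]:
    """Call bound segments: maximal runs of >= ``n_min`` consecutive
    localizations all within ``r_max`` (µm) of the run's centroid.

    The dwell of a run of L frames is ``(L - 1) * frame_interval``: only
    elapsed time between the first and last bound frame is observed.
    Runs that reach the last movie frame are flagged censored.
    """
    if not (r_max > 0):
        raise ValueError(f"r_max must be > 0, got {r_max}")
    if n_min < 2:
        raise ValueError("n_min must be >= 2")
    dt = ts.meta.frame_interval
    last_frame = ts.meta.n_frames - 1
    if last_frame < 0:
        last_frame = max((int(tr.frames.max()) for tr in ts), default=0)
    segments: list[BoundSegment] = []
    for tr in ts:
        n = len(tr)
        i = 0
        while i < n:
            j = i
            sx, sy = tr.x[i], tr.y[i]
            # grow the run while every member stays within r_max of the
            # running centroid and frames remain consecutive
            while j + 1 < n and tr.frames[j + 1] == tr.frames[j] + 1:
                cx = (sx + tr.x[j + 1]) / (j + 2 - i)
                cy = (sy + tr.y[j + 1]) / (j + 2 - i)
                dx = tr.x[i : j + 2] - cx
                dy = tr.y[i : j + 2] - cy
                if np.max(dx * dx + dy * dy) > r_max * r_max:
                    break
                j += 1
                sx += tr.x[j]
                sy += tr.y[j]
            run = j - i + 1
            if run >= n_min:
                segments.append(
                    BoundSegment(
                        track_id=tr.track_id,
                        start_frame=int(tr.frames[i]),
                        end_frame=int(tr.frames[j]),
                        dwell=(run - 1) * dt,
                        censored_at_movie_end=int(tr.frames[j]) >= last_frame,
                    )
                )
            i = j + 1
    return segments


# ---------------------------------------------------------------------------
# survival curve


def build_survival(segments: list[BoundSegment], ts: TrackSet) -> SurvivalCurve:
    """Count dwell times into a survival curve normalized to C_eq.

    ``S_raw(t) = #(dwell >= t) / n0`` on a grid of frame-interval
    multiples spanning the observed dwells, then scaled so that the first
    grid point equals the bound fraction ``C_eq`` = (number of detections
    in bound segments) / (total detections in all movie frames).
    Censored segments count up to their observed dwell.
    """
    if not segments:
        raise ValueError("no bound segments: nothing to build a survival curve from")
    dt = ts.meta.frame_interval
    dwell_frames = np.array([int(round(s.dwell / dt)) for s in segments])
    n0 = len(segments)
    k_min = int(dwell_frames.min())
    k_max = int(dwell_frames.max())
    ks = np.arange(k_min, k_max + 1)
    counts = np.array([(dwell_frames >= k).sum() for k in ks], dtype=float)
    s_raw = counts / n0
    bound_detections = sum(s.n_frames for s in segments)
    total_detections = ts.n_localizations
    if total_detections <= 0:
        raise ValueError("TrackSet holds no detections")
    c_eq = min(1.0, bound_detections / total_detections)
    n_frames = ts.meta.n_frames or (1 + max(int(tr.frames.max()) for tr in ts))
    per_frame = np.zeros(n_frames)
    for tr in ts:
        valid = tr.frames[tr.frames < n_frames]
        per_frame[valid] += 1
    return SurvivalCurve(
        times=ks * dt,
        S=c_eq * s_raw,
        counts=counts,
        n0=n0,
        C_eq=c_eq,
        frame_interval=dt,
        normalization="bound_fraction",
        correction="none",
        detections_per_frame=per_frame,
        provenance={"n_censored": int(sum(s.censored_at_movie_end for s in segments))},
    )


def _invvar_weights(counts: np.ndarray) -> np.ndarray:
    """Inverse-variance weights for log S under binomial counting noise.

    Var[log S(t)] ~ (1 - S)/(n0 S) with S the raw surviving fraction, so
    the weight is counts/(1 - S), regularized at the first grid point
    where S = 1 exactly.  To leading order (S well below 1) this is
    proportional to the surviving counts.
    """
    n0 = counts[0]
    s = counts / n0
    return counts / (1.0 - s + 1.0 / n0)


def _fit_exp_mixture(
    times: np.ndarray,
    S: np.ndarray,
    weights: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_starts: int = 5,
):
    """Weighted log-space fit of S(t) = sum_i A_i exp(-t / tau_i).

    Returns (amplitudes, taus, weighted RSS) or None if no start converges.
    Initial taus are log-spaced between the grid spacing and the grid span,
    jittered per start.
    """
    t0, t1 = times[0], times[-1]
    lo = max(t0, 1e-6)
    hi = max(t1, lo * 10)
    logS = np.log(S)
    sw = np.sqrt(weights)

    def residual(p):
        model = np.zeros_like(times)
        for i in range(k):
            model += p[f"A{i}"].value * np.exp(-times / p[f"tau{i}"].value)
        return sw * (np.log(np.clip(model, 1e-300, None)) - logS)

    best = None
    base_taus = np.logspace(math.log10(lo), math.log10(hi), k + 2)[1:-1]
    for start in range(n_starts):
        p = lmfit.Parameters()
        jitter = rng.uniform(0.3, 3.0, size=k) if start else np.ones(k)
        for i in range(k):
            p.add(f"A{i}", value=S[0] / k, min=0.0)
            p.add(f"tau{i}", value=base_taus[i] * jitter[i], min=lo / 100, max=hi * 100)
        try:
            res = lmfit.minimize(residual, p, method="least_squares")
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[2]:
            amps = np.array([res.params[f"A{i}"].value for i in range(k)])
            taus = np.array([res.params[f"tau{i}"].value for i in range(k)])
            order = np.argsort(taus)
            best = (amps[order], taus[order], rss)
    return best


def _fit_power(times, S, weights, rng, n_starts=5):
    logS = np.log(S)
    sw = np.sqrt(weights)

    def residual(p):
        model = p["A"].value * times ** (-p["beta"].value)
        return sw * (np.log(np.clip(model, 1e-300, None)) - logS)

    best = None
    for start in range(n_starts):
        p = lmfit.Parameters()
        b0 = 0.5 * (rng.uniform(0.2, 4.0) if start else 1.0)
        p.add("A", value=S[0] * times[0] ** b0, min=0.0)
        p.add("beta", value=b0, min=1e-3, max=10.0)
        try:
            res = lmfit.minimize(residual, p, method="least_squares")
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[2]:
            best = (res.params["A"].value, res.params["beta"].value, rss)
    return best


def _fit_hybrid(times, S, weights, rng, n_starts=5):
    t0, t1 = times[0], times[-1]
    lo = max(t0, 1e-6)
    hi = max(t1, lo * 10)
    logS = np.log(S)
    sw = np.sqrt(weights)

    def residual(p):
        model = p["A1"].value * np.exp(-times / p["tau1"].value) + p["A2"].value * times ** (
            -p["beta"].value
        )
        return sw * (np.log(np.clip(model, 1e-300, None)) - logS)

    best = None
    for start in range(n_starts):
        p = lmfit.Parameters()
        tau0 = np.exp(rng.uniform(math.log(lo), math.log(hi))) if start else math.sqrt(lo * hi)
        b0 = rng.uniform(0.2, 2.0) if start else 0.7
        p.add("A1", value=0.6 * S[0], min=0.0)
        p.add("tau1", value=tau0, min=lo / 100, max=hi * 100)
        p.add("A2", value=0.4 * S[0] * times[0] ** b0, min=0.0)
        p.add("beta", value=b0, min=1e-3, max=10.0)
        try:
            res = lmfit.minimize(residual, p, method="least_squares")
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[1]:
            best = (
                {k: res.params[k].value for k in ("A1", "tau1", "A2", "beta")},
                rss,
            )
    return best


N_PARAMS = {"exp_1": 2, "exp_2": 4, "exp_3": 6, "power_law": 2, "power_plus_exp": 4}


def _eval_family(family: str, params: dict, t: np.ndarray) -> np.ndarray:
    """Evaluate a fitted dwell model S(t) at times t."""
    t = np.asarray(t, dtype=float)
    if family.startswith("exp_"):
        k = int(family.split("_")[1])
        return sum(params[f"A{i}"] * np.exp(-t / params[f"tau{i}"]) for i in range(k))
    if family == "power_law":
        return params["A"] * t ** (-params["beta"])
    return params["A1"] * np.exp(-t / params["tau1"]) + params["A2"] * t ** (
        -params["beta"]
    )


def _bic(family: str, params: dict, curve: "SurvivalCurve") -> float:
    """BIC from the multinomial likelihood of the binned dwell counts.

    The survival curve's grid points are cumulative counts, so their
    residuals are strongly correlated; a residual-based likelihood vastly
    overstates the evidence for extra components.  The per-bin dwell
    counts (successive differences of the surviving counts, plus the tail
    bin) are independent, so the model likelihood is evaluated on them:
    p_k = [S(t_k) - S(t_k+1)] / S(t_0), with the final grid point holding
    the tail mass S(t_last)/S(t_0).  For corrected curves the fitted
    model is re-multiplied by the recorded bleaching factor so that it
    predicts the *observed* counts.  n in the k*ln(n) penalty is the
    number of dwell segments.
    """
    counts = curve.counts
    m = np.empty(len(counts))
    m[:-1] = counts[:-1] - counts[1:]
    m[-1] = counts[-1]
    model = _eval_family(family, params, curve.times)
    if curve.bleach_factor is not None:
        model = model * curve.bleach_factor
    model = np.clip(model, 1e-300, None)
    p = np.empty(len(counts))
    p[:-1] = model[:-1] - model[1:]
    p[-1] = model[-1]
    p = np.clip(p / model[0], 1e-300, None)
    lnL = float(np.sum(m * np.log(p)))
    return N_PARAMS[family] * math.log(max(curve.n0, 2)) - 2.0 * lnL


def fit_dwell_models(
    curve: SurvivalCurve,
    families: tuple[str, ...] = FAMILIES,
    seed: int = 0,
    n_starts: int = 5,
    hybrid_margin: float = 2.0,
    min_counts: float = 3,
) -> tuple[list[DwellModelFit], DwellModelFit]:
    """Fit all dwell-model families to a survival curve; select by BIC.

    Fitting is weighted least squares on log S with inverse-variance
    weights (counts/(1 - S) under binomial counting noise; proportional
    to surviving counts once S is well below 1).  Grid points with fewer
    than ``min_counts`` surviving segments are excluded: below a few
    counts the log-S noise is strongly skewed and biases tau upward.  Each family is fitted from
    ``n_starts`` initializations (taus log-spaced over the grid span,
    jittered by a seeded RNG).  The hybrid (power law + exponential)
    model is accepted only if its BIC beats both of its parents (exp_1
    and power_law) by at least ``hybrid_margin``: a guard against its
    weak identifiability.

    Returns (all fits, selected best).  Families whose every start fails
    are excluded from selection; if all fail, a RuntimeError is raised.
    """
    mask = (curve.S > 0) & (curve.counts >= min_counts)
    times = curve.times[mask]
    S = curve.S[mask]
    weights = _invvar_weights(curve.counts)[mask]
    if len(times) < 8:
        raise ValueError("need >= 8 positive grid points to fit dwell models")
    rng = np.random.default_rng(seed)
    fits: list[DwellModelFit] = []
    n = len(times)
    for fam in families:
        if fam.startswith("exp_"):
            k = int(fam.split("_")[1])
            out = _fit_exp_mixture(times, S, weights, k, rng, n_starts)
            if out is None:
                fits.append(_failed(fam, n))
                continue
            amps, taus, rss = out
            tot = amps.sum()
            fracs = amps / tot if tot > 0 else np.full(k, np.nan)
            params_d = {
                **{f"A{i}": float(amps[i]) for i in range(k)},
                **{f"tau{i}": float(taus[i]) for i in range(k)},
            }
            fits.append(
                DwellModelFit(
                    family=fam,
                    params=params_d,
                    fractions=tuple(float(f) for f in fracs),
                    taus=tuple(float(t) for t in taus),
                    bic=_bic(fam, params_d, curve),
                    n_points=n,
                    rss_weighted=rss,
                )
            )
        elif fam == "power_law":
            out = _fit_power(times, S, weights, rng, n_starts)
            if out is None:
                fits.append(_failed(fam, n))
                continue
            A, beta, rss = out
            params_d = {"A": float(A), "beta": float(beta)}
            fits.append(
                DwellModelFit(
                    family=fam,
                    params=params_d,
                    fractions=(1.0,),
                    taus=(),
                    bic=_bic(fam, params_d, curve),
                    n_points=n,
                    rss_weighted=rss,
                )
            )
        elif fam == "power_plus_exp":
            out = _fit_hybrid(times, S, weights, rng, n_starts)
            if out is None:
                fits.append(_failed(fam, n))
                continue
            params, rss = out
            t0 = times[0]
            comp_exp = params["A1"] * math.exp(-t0 / params["tau1"])
            comp_pow = params["A2"] * t0 ** (-params["beta"])
            tot = comp_exp + comp_pow
            params_d = {k: float(v) for k, v in params.items()}
            fits.append(
                DwellModelFit(
                    family=fam,
                    params=params_d,
                    fractions=(
                        (float(comp_exp / tot), float(comp_pow / tot))
                        if tot > 0
                        else (np.nan, np.nan)
                    ),
                    taus=(float(params["tau1"]),),
                    bic=_bic(fam, params_d, curve),
                    n_points=n,
                    rss_weighted=rss,
                )
            )
        else:
            raise ValueError(f"unknown family {fam!r}")

    ok = {f.family: f for f in fits if f.success}
    if not ok:
        raise RuntimeError("all dwell-model families failed to converge")
    candidates = dict(ok)
    hyb = candidates.get("power_plus_exp")
    if hyb is not None:
        for parent in ("exp_1", "power_law"):
            if parent in ok and not (hyb.bic <= ok[parent].bic - hybrid_margin):
                candidates.pop("power_plus_exp", None)
                break
    best = min(candidates.values(), key=lambda f: f.bic)
    return fits, best


def _failed(family: str, n: int) -> DwellModelFit:
    return DwellModelFit(
        family=family,
        params={},
        fractions=(),
        taus=(),
        bic=math.inf,
        n_points=n,
        rss_weighted=math.inf,
        success=False,
        message="no start converged",
    )


# ---------------------------------------------------------------------------
# photobleaching correction

CORRECTION_METHODS = ("intrinsic", "whole_reference", "immobile_fraction")


def correct_photobleaching(
    curve: SurvivalCurve,
    method: str,
    reference: SurvivalCurve | np.ndarray | None = None,
    seed: int = 0,
) -> SurvivalCurve:
    """Remove the photobleaching component from a survival curve.

    ``intrinsic``
        Fit a single exponential to the target's own per-frame detection
        counts versus cumulative exposure count and divide S by it.  Pass
        a per-frame count array as ``reference`` to override the counts
        stored on the curve.
    ``whole_reference``
        Divide S pointwise by the reference species' survival curve
        normalized to 1 at its first point (e.g. total histone H3).
    ``immobile_fraction``
        Fit the reference survival with a tri-exponential, take its
        slowest component normalized to 1 at t = 0 as the bleaching
        curve, and divide S by it.  A warning is recorded in provenance
        when the slowest reference tau is not separated (< 2x the next).

    In every case the corrected S is re-clipped so its first point does
    not exceed C_eq, and the correction method is recorded.
    """
    if method not in CORRECTION_METHODS:
        raise ValueError(f"method must be one of {CORRECTION_METHODS}, got {method!r}")
    prov = dict(curve.provenance)
    warnings: list[str] = list(prov.get("warnings", []))
    ks = np.rint(curve.times / curve.frame_interval).astype(int)

    if method == "intrinsic":
        counts = (
            np.asarray(reference, dtype=float)
            if reference is not None and not isinstance(reference, SurvivalCurve)
            else curve.detections_per_frame
        )
        if counts is None:
            raise ValueError("intrinsic correction needs per-frame detection counts")
        lam = _intrinsic_bleach_rate(counts)
        bleach = np.exp(-lam * ks)  # ks = exposures elapsed over the dwell
        prov["bleach_rate_per_exposure"] = float(lam)
    elif method == "whole_reference":
        if not isinstance(reference, SurvivalCurve):
            raise ValueError("whole_reference correction needs a reference SurvivalCurve")
        ref_ks = np.rint(reference.times / reference.frame_interval).astype(int)
        if not math.isclose(reference.frame_interval, curve.frame_interval, rel_tol=1e-9):
            raise ValueError("reference and target frame intervals differ")
        if ref_ks[-1] < ks[-1]:
            raise ValueError("reference survival curve is shorter than the target grid")
        lookup = dict(zip(ref_ks.tolist(), (reference.S / reference.S[0]).tolist()))
        try:
            bleach = np.array([lookup[int(k)] for k in ks])
        except KeyError as e:
            raise ValueError(f"reference grid is missing dwell bin {e}") from e
        prov["reference_n0"] = reference.n0
    else:  # immobile_fraction
        if not isinstance(reference, SurvivalCurve):
            raise ValueError("immobile_fraction correction needs a reference SurvivalCurve")
        if reference.times[-1] < curve.times[-1]:
            raise ValueError("reference survival curve is shorter than the target grid")
        mask = (reference.S > 0) & (reference.counts >= 3)
        out = _fit_exp_mixture(
            reference.times[mask],
            reference.S[mask],
            _invvar_weights(reference.counts)[mask],
            k=3,
            rng=np.random.default_rng(seed),
        )
        if out is None:
            raise RuntimeError("tri-exponential fit of the reference failed")
        amps, taus, _ = out
        # ignore vanishing components before picking the slowest
        real = amps > 1e-3 * amps.sum()
        taus_r = taus[real]
        tau_slow = float(taus_r[-1])
        if len(taus_r) > 1 and tau_slow < 2.0 * float(taus_r[-2]):
            warnings.append(
                f"slowest reference tau {tau_slow:.3g}s not separated "
                f"(< 2x next tau {taus_r[-2]:.3g}s)"
            )
        bleach = np.exp(-curve.times / tau_slow)
        prov["reference_tau_slow_s"] = tau_slow
        prov["reference_taus_s"] = [float(t) for t in taus]

    bleach = np.clip(bleach, 1e-300, None)
    S = curve.S / bleach
    if S[0] > curve.C_eq > 0:
        S = S * (curve.C_eq / S[0])
    prov["warnings"] = warnings
    return replace(
        curve,
        S=S,
        correction=method,
        bleach_factor=bleach / bleach[0],
        provenance=prov,
        detections_per_frame=curve.detections_per_frame,
    )


def _intrinsic_bleach_rate(counts: np.ndarray) -> float:
    """Per-exposure bleach rate from a single-exponential fit of per-frame
    detection counts vs cumulative exposure count (weighted log-linear)."""
    n = np.arange(len(counts), dtype=float)
    pos = counts > 0
    if pos.sum() < 2:
        raise ValueError("not enough nonzero detection counts to fit bleaching")
    w = counts[pos]
    coef = np.polyfit(n[pos], np.log(counts[pos]), 1, w=np.sqrt(w))
    return float(max(-coef[0], 0.0))


# ---------------------------------------------------------------------------
# derived kinetics


def derive_kinetics(
    fit: DwellModelFit,
    C_eq: float,
    S_eq: float | None = None,
) -> BindingKinetics:
    """Derive binding kinetics from a bi-exponential dwell fit.

    The short-tau component is read as non-specific binding and the
    long-tau one as specific binding.  Computes::

        tau_res    = F_NS/(F_NS+F_S) * tau_NS + F_S/(F_NS+F_S) * tau_S
        tau_search = (1 - C_eq)/C_eq * tau_res
        N_trials   = (F_S + F_NS)/F_S
        k_on*      = 1/tau_search        (pseudo on-rate)
        k_on       = k_on*/S_eq          (only when S_eq is given)

    Raises on power-law fits — no specific residence time is defined for
    a power-law dwell distribution — and on degenerate C_eq in {0, 1}.
    """
    if fit.family in ("power_law", "power_plus_exp"):
        raise ValueError(
            "No specific residence times can be estimated from Power Law fits; "
            "derive_kinetics requires a bi-exponential (exp_2) model"
        )
    if fit.family != "exp_2":
        raise ValueError(f"derive_kinetics requires an exp_2 fit, got {fit.family}")
    if not (0.0 < C_eq < 1.0):
        raise ValueError(f"C_eq must be strictly inside (0, 1), got {C_eq}")
    (f_ns, f_s) = fit.fractions  # sorted by tau: short (NS) first
    (tau_ns, tau_s) = fit.taus
    tot = f_ns + f_s
    if tot <= 0 or f_s <= 0:
        raise ValueError("bound fractions must be positive")
    tau_res = (f_ns / tot) * tau_ns + (f_s / tot) * tau_s
    assert min(tau_ns, tau_s) - 1e-12 <= tau_res <= max(tau_ns, tau_s) + 1e-12, (
        "tau_res must be a convex combination of tau_NS and tau_S"
    )
    tau_search = (1.0 - C_eq) / C_eq * tau_res
    n_trials = tot / f_s
    k_on_star = 1.0 / tau_search
    k_on = None
    if S_eq is not None:
        if not (0.0 < S_eq <= 1.0):
            raise ValueError(f"S_eq must be in (0, 1], got {S_eq}")
        k_on = k_on_star / S_eq
    return BindingKinetics(
        C_eq=C_eq,
        F_NS=f_ns,
        F_S=f_s,
        tau_NS=tau_ns,
        tau_S=tau_s,
        tau_res=tau_res,
        tau_search=tau_search,
        n_trials=n_trials,
        k_on_star=k_on_star,
        k_off_NS=1.0 / tau_ns,
        k_off_S=1.0 / tau_s,
        S_eq=S_eq,
        k_on=k_on,
    )
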