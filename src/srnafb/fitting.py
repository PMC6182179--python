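"""Least-squares identification of circuit parameters from dose-response
tables.

Rates span decades and are strictly positive, so the search runs in
log10-parameter space with bounds, and residuals are log10 differences
between predicted (gain x steady-state output) and observed replicate
geometric means.  A Latin-hypercube multistart guards against local
minima; everything is deterministic given the seed.

Practical identifiability: with steady-state data alone only certain
parameter combinations are constrained (e.g. ``a1 * kappa`` sets the
output scale, and in the weak-binding regime only the product ``k * b1``
of duplex formation rate and sRNA transcription is visible).  The default
specs therefore freeze ``kappa`` and ``k`` at literature-style values and
fit the remaining channel parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.stats import qmc

from .circuits import (
    CircuitParams,
    CircuitTopology,
    InducerInput,
    TopologyKind,
)
from .cytometry import DoseResponseTable
from .dynamics import SteadyStateError, steady_state

__all__ = [
    "FitSpec",
    "FitResult",
    "RecoveryReport",
    "DEFAULT_BOUNDS",
    "residual",
    "fit",
    "carry_over",
    "recovery_report",
    "default_fit_spec",
    "overlay_table",
]

logger = logging.getLogger(__name__)

# Broad log-space search boxes per parameter (linear units).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "a0": (1e-4, 1.0),
    "a1": (1e-2, 1e2),
    "K_R": (1.0, 1e4),
    "n_R": (1.0, 6.0),
    "K_A": (1.0, 1e5),
    "n_A": (1.0, 6.0),
    "theta1": (0.1, 1e3),
    "n1": (1.0, 6.0),
    "theta2": (1e-6, 1e-1),
    "n2": (1.0, 6.0),
    "theta3": (1e-3, 10.0),
    "n3": (1.0, 6.0),
    "b0": (1e-6, 1.0),
    "b1": (1e-2, 1e4),
    "kappa": (0.1, 1e3),
    "k": (1e-4, 10.0),
    "delta_m": (1e-3, 10.0),
    "delta_s": (1e-3, 10.0),
    "delta_c": (1e-3, 10.0),
    "delta_p": (1e-4, 1.0),
    "omega": (1e-2, 1e4),
    "gain": (1e-3, 1e3),
}


@dataclass(frozen=True)
class FitSpec:
    """What to fit: free parameters with bounds, frozen values, data."""

    topology: CircuitTopology
    free: dict[str, tuple[float, float]]
    frozen: dict[str, float]
    data: DoseResponseTable
    gain: float = 1.0
    multistart: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        names = set(CircuitParams.field_names())
        free = set(self.free) - {"gain"}
        frozen = set(self.frozen)
        if free & frozen:
            raise ValueError(f"parameters both free and frozen: {sorted(free & frozen)}")
        if free | frozen != names:
            missing = names - (free | frozen)
            extra = (free | frozen) - names
            raise ValueError(
                f"free+frozen must cover the parameter set exactly; "
                f"missing {sorted(missing)}, unknown {sorted(extra)}")
        for name, (lo, hi) in self.free.items():
            if not (0 < lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters with convergence diagnostics."""

    params: CircuitParams
    gain: float
    rss: float
    per_start_rss: tuple[float, ...]
    converged: bool
    seed: int
    free_names: tuple[str, ...]

    def to_yaml(self, path: str | None = None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "gain": float(self.gain),
            "rss": float(self.rss),
            "per_start_rss": [float(r) for r in self.per_start_rss],
            "converged": bool(self.converged),
            "seed": int(self.seed),
            "free_names": list(self.free_names),
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _predictions(params: CircuitParams, topology: CircuitTopology,
                 data: DoseResponseTable) -> np.ndarray:
    """Steady-state output per table row, cached per unique condition."""
    cache: dict[tuple[float, float, float], float] = {}
    preds = np.empty(len(data.data))
    for i, row in enumerate(data.data.itertuples(index=False)):
        key = (row.u1, row.u2, row.u3)
        if key not in cache:
            try:
                cache[key] = steady_state(topology, params,
                                          InducerInput(*key)).p
            except SteadyStateError as exc:
                raise SteadyStateError(
                    f"steady state failed at condition {row.condition_id} "
                    f"(u1={row.u1}, u2={row.u2}, u3={row.u3})") from exc
        preds[i] = cache[key]
    return preds


def residual(params: CircuitParams, topology: CircuitTopology,
             data: DoseResponseTable, gain: float) -> np.ndarray:
    """Log10 residuals, one per (condition, replicate) geometric mean."""
    preds = gain * _predictions(params, topology, data)
    preds = np.maximum(preds, 1e-300)
    obs = data.data["geo_mean"].to_numpy()
    return np.log10(preds) - np.log10(obs)


def fit(spec: FitSpec) -> FitResult:
    """Bounded nonlinear least squares in log-parameter space from a
    seeded Latin-hypercube multistart; returns the best start."""
    names = sorted(spec.free)
    if not names:
        params = CircuitParams.from_dict(spec.frozen)
        r = residual(params, spec.topology, spec.data, spec.gain)
        rss = float(np.dot(r, r))
        return FitResult(params=params, gain=spec.gain, rss=rss,
                         per_start_rss=(rss,), converged=True, seed=spec.seed,
                         free_names=())
    if len(spec.data) < len(names):
        raise ValueError("fewer residual elements than free parameters")
    lo = np.log10([spec.free[n][0] for n in names])
    hi = np.log10([spec.free[n][1] for n in names])

    def unpack(x: np.ndarray) -> tuple[CircuitParams, float]:
        vals = dict(spec.frozen)
        gain = spec.gain
        for n, xv in zip(names, 10.0 ** x):
            if n == "gain":
                gain = xv
            else:
                vals[n] = xv
        return CircuitParams.from_dict(vals), gain

    def objective(x: np.ndarray) -> np.ndarray:
        params, gain = unpack(x)
        return residual(params, spec.topology, spec.data, gain)

    starts = [0.5 * (lo + hi)]
    if spec.multistart > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
        unit = sampler.random(spec.multistart - 1)
        starts.extend(lo + unit * (hi - lo))

    best = None
    per_start: list[float] = []
    failures: list[str] = []
    for x0 in starts:
        try:
            sol = least_squares(objective, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except (SteadyStateError, ValueError) as exc:
            failures.append(str(exc))
            per_start.append(float("inf"))
            continue
        rss = float(2.0 * sol.cost)
        per_start.append(rss)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("all fit starts failed: " + "; ".join(failures))
    rss, sol = best
    params, gain = unpack(sol.x)
    return FitResult(params=params, gain=gain, rss=rss,
                     per_start_rss=tuple(per_start),
                     converged=bool(sol.status > 0), seed=spec.seed,
                     free_names=tuple(names))


def carry_over(source: FitResult, target_spec: FitSpec,
               shared: set[str] | frozenset[str]) -> FitSpec:
    """Freeze shared parameters of the target at the source's fitted
    values, mirroring parameter carry-over between circuit variants."""
    valid = set(CircuitParams.field_names()) | {"gain"}
    unknown = set(shared) - valid
    if unknown:
        raise KeyError(f"shared parameters not in the source fit: {sorted(unknown)}")
    free = dict(target_spec.free)
    frozen = dict(target_spec.frozen)
    gain = target_spec.gain
    for name in sorted(shared):
        if name == "gain":
            gain = source.gain
            free.pop("gain", None)
            continue
        frozen[name] = getattr(source.params, name)
        free.pop(name, None)
    return replace(target_spec, free=free, frozen=frozen, gain=gain)


@dataclass(frozen=True)
class RecoveryReport:
    """Relative errors of fitted vs true parameters."""

    relative: dict[str, float]
    absolute_fallback: frozenset[str]
    max_relative: float


def recovery_report(truth: CircuitParams, fitted: CircuitParams,
                    free_names: tuple[str, ...] | list[str]) -> RecoveryReport:
    """Per-parameter |fitted - truth| / truth over the free set; a zero
    truth value falls back to the absolute error and is flagged."""
    rel: dict[str, float] = {}
    fallback = set()
    for name in free_names:
        if name == "gain":
            continue
        t = getattr(truth, name)
        f = getattr(fitted, name)
        if t == 0:
            rel[name] = abs(f - t)
            fallback.add(name)
        else:
            rel[name] = abs(f - t) / abs(t)
    max_rel = max((v for k, v in rel.items() if k not in fallback), default=0.0)
    return RecoveryReport(relative=rel, absolute_fallback=frozenset(fallback),
                          max_relative=max_rel)


def default_fit_spec(topology: CircuitTopology, data: DoseResponseTable,
                     gain: float = 1.0, gain_free: bool = False,
                     multistart: int = 8, seed: int = 0,
                     base: CircuitParams | None = None) -> FitSpec:
    """The package's default free/frozen split per topology.

    Degradation rates, translation and duplex-formation rates are frozen
    (literature-style values); the promoter and inducer-coupling
    parameters of the exercised channels are fitted.
    """
    from .circuits import default_params

    base = base or default_params(topology)
    if topology.kind is TopologyKind.AUTOREPRESSOR:
        free_names = ["a0", "a1", "K_R", "n_R", "theta1", "n1"]
    elif topology.kind is TopologyKind.SRNA_TUNED_AUTOREPRESSOR:
        free_names = ["a1", "b1", "theta2", "n2"]
    else:
        free_names = ["a1", "b1", "K_A", "n_A"]
    free = {n: DEFAULT_BOUNDS[n] for n in free_names}
    if gain_free:
        free["gain"] = DEFAULT_BOUNDS["gain"]
    frozen = {n: getattr(base, n) for n in CircuitParams.field_names()
              if n not in free_names}
    return FitSpec(topology=topology, free=free, frozen=frozen, data=data,
                   gain=gain, multistart=multistart, seed=seed)


def overlay_table(result: FitResult, topology: CircuitTopology,
                  data: DoseResponseTable):
    """Observed vs predicted geometric means per (condition, replicate),
    for parity plots against the experimental figures."""
    df = data.data.copy()
    df["predicted"] = result.gain * _predictions(result.params, topology, data)
    return df[["condition_id", "u1", "u2", "u3", "replicate", "geo_mean",
               "predicted"]].rename(columns={"geo_mean": "observed"})
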