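"""Numerical integration, steady-state detection, and derived summaries."""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core import CompiledRHS, NetworkSpec, ParameterSet, assemble_rhs

__all__ = [
    "IntegrationError",
    "Trajectory",
    "SteadyStateRecord",
    "integrate",
    "steady_state",
    "derived_summaries",
]

NEG_TOL = 1e-6  # entries in [-NEG_TOL, 0) are solver overshoot: clipped to 0


class IntegrationError(RuntimeError):
    pass


def _params_hash(params: ParameterSet) -> str:
    blob = ",".join(f"{k}={params[k]:.17g}" for k in sorted(params))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class Trajectory:
    """Time-indexed sequence of system states (times in days)."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_nodes)
    node_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def series(self, node: str) -> np.ndarray:
        return self.states[:, self.node_names.index(node)]

    def to_frame(self):
        """Tidy long-format table: columns time, node, value."""
        import pandas as pd

        n_t = len(self.times)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, len(self.node_names)),
                "node": list(self.node_names) * n_t,
                "value": self.states.ravel(),
            }
        )


@dataclass
class SteadyStateRecord:
    """A converged (or timed-out) end state plus derived summaries."""

    state: np.ndarray
    converged: bool
    residual: float
    t_final: float
    derived: dict = field(default_factory=dict)


def _clip_negatives(states: np.ndarray, rhs: CompiledRHS) -> np.ndarray:
    low = states.min()
    if low < -NEG_TOL:
        worst = np.unravel_index(states.argmin(), states.shape)
        name = rhs.network.node_names[worst[1]]
        raise IntegrationError(
            f"state {name!r} reached {low:.3e} (below -{NEG_TOL:g}); "
            "the system is likely mis-parameterized or too stiff for the "
            "requested tolerances"
        )
    return np.clip(states, 0.0, None)


def integrate(
    network: NetworkSpec,
    params: ParameterSet,
    x0: np.ndarray,
    t_end: float,
    *,
    rhs: CompiledRHS | None = None,
    frozen_ia: float | None = None,
    method: str = "LSODA",
    rtol: float = 1e-6,
    atol: float = 1e-9,
    t_eval: np.ndarray | None = None,
    metadata: dict | None = None,
) -> Trajectory:
    """Integrate the assembled system with a stiff-capable variable-step
    method (LSODA by default, BDF available).

    Entries that dip below ``-1e-6`` (well beyond accumulated solver
    overshoot at the default tolerances) raise :class:`IntegrationError`;
    smaller negative excursions are clipped to zero.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.min() < 0:
        raise ValueError("initial state must be nonnegative")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    f = rhs if rhs is not None else assemble_rhs(network, params, frozen_ia=frozen_ia)
    sol = solve_ivp(
        f, (0.0, float(t_end)), x0, method=method, rtol=rtol, atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        final = sol.y[:, -1] if sol.y.size else x0
        stiffest = int(np.argmax(np.abs(f(sol.t[-1] if sol.t.size else 0.0, final))))
        raise IntegrationError(
            f"solver {method} failed at t={sol.t[-1] if sol.t.size else 0:.3g}: "
            f"{sol.message} (largest residual component: "
            f"{f.network.node_names[stiffest]!r})"
        )
    states = _clip_negatives(sol.y.T.copy(), f)
    meta = {"params_hash": _params_hash(params), "method": method}
    if frozen_ia is not None:
        meta["frozen_ia"] = frozen_ia
    meta.update(metadata or {})
    return Trajectory(sol.t, states, f.network.node_names, meta)


def steady_state(
    network: NetworkSpec,
    params: ParameterSet,
    x0: np.ndarray,
    t_max: float = 2000.0,
    tol: float = 1e-6,
    *,
    window: float = 100.0,
    frozen_ia: float | None = None,
    method: str = "LSODA",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> SteadyStateRecord:
    """Integrate in windows until ``max |dx/dt| < tol`` (per day) or ``t_max``.

    Never raises on non-convergence (e.g. a sustained oscillation); the
    record's ``converged`` flag reports the outcome.
    """
    rhs = assemble_rhs(network, params, frozen_ia=frozen_ia)
    x = np.asarray(x0, dtype=float)
    t = 0.0
    converged = False
    residual = float(np.max(np.abs(rhs(0.0, x))))
    if residual < tol:
        converged = True
    while not converged and t < t_max:
        step = min(window, t_max - t)
        traj = integrate(
            network, params, x, step, rhs=rhs, method=method,
            rtol=rtol, atol=atol, t_eval=np.array([0.0, step]),
        )
        x = traj.final
        t += step
        residual = float(np.max(np.abs(rhs(t, x))))
        if residual < tol:
            converged = True
    record = SteadyStateRecord(
        state=x, converged=converged, residual=residual, t_final=t,
    )
    record.derived = derived_summaries(x, network, params, frozen_ia=frozen_ia)
    return record


def derived_summaries(
    state: np.ndarray,
    network: NetworkSpec,
    params: ParameterSet,
    frozen_ia: float | None = None,
) -> dict:
    """Aggregate read-outs of a state vector.

    Returns total tumor (over all compartments), killer T total, CAF, the
    PDL1-/PDL1+ tumor ratio (``inf`` with ``pdl1_ratio_defined=False`` when no
    PDL1+ cells remain), the instantaneous accessibility index, and the same
    quantities normalized by their carrying capacities (used by the subtype
    classifier).
    """
    names = network.node_names
    idx = {n: i for i, n in enumerate(names)}

    def total(group: str) -> float:
        return float(sum(state[idx[m]] for m in network.members(group)))

    tumor = total("tumor") if "tumor" in network.groups else 0.0
    killer = total("TK") if "TK" in network.groups else 0.0
    caf = float(state[idx["CAF"]]) if "CAF" in idx else 0.0
    cn = total("Cn") if "Cn" in network.groups else 0.0
    cp = total("Cp") if "Cp" in network.groups else 0.0
    if cp > 0:
        ratio, defined = cn / cp, True
    else:
        ratio, defined = math.inf, False

    if frozen_ia is not None:
        ia = frozen_ia
    elif all(k in params for k in ("alpha_acc", "Kbr")) and "CAF" in idx:
        ia = 1.0 - math.tanh(params["alpha_acc"] * caf * params["Kbr"])
    else:
        ia = 1.0

    out = {
        "total_tumor": tumor,
        "killer_T_total": killer,
        "CAF": caf,
        "pdl1_ratio": ratio,
        "pdl1_ratio_defined": defined,
        "Ia": ia,
    }
    if "xmax_tumor" in params:
        out["tumor_frac"] = tumor / params["xmax_tumor"]
    if "xmax_TK" in params:
        out["killer_frac"] = killer / params["xmax_TK"]
    if "xmax_fib" in params:
        out["caf_frac"] = caf / params["xmax_fib"]
    return out
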