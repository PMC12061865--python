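"""Stochastic integration of the coupled two-region system.

The state is 8-dimensional: per region (PFC, SCC) the NMDA and GABA gating
fractions S_E, S_I, the serotonergic current variable M and the extracellular
serotonin concentration (nM).  Gating variables receive additive Gaussian
noise with Euler-Maruyama sqrt(step) scaling in the parameter tables'
millisecond frame (see :func:`noise_step_scale`); the serotonergic current
and serotonin kinetics are integrated deterministically.

The integrator is vectorized over independent "systems" (replicates and/or
conditions): parameters are packed into arrays of shape (n_systems, 2) and a
whole replicate batch advances one time step per numpy operation.  Each
system owns a counter-based random stream (Philox keyed by its seed), so a
replicate's trajectory is bit-identical whether it runs alone or inside a
batch.

A noise-free fixed point of the full coupled system is available from
:func:`steady_state_oracle` and serves as the deterministic reference for
the stochastic summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .model_core import SystemState, inflammation_factors, transfer_rate
from .params import ModelParams, SimulationSettings

__all__ = [
    "TrajectorySummary",
    "ConditionSummary",
    "SimulationDiverged",
    "euler_maruyama_step",
    "run_trajectory",
    "run_replicates",
    "steady_state_oracle",
]

_DIVERGENCE_BOUND = 1e6
_NOISE_BLOCK = 1024  # steps of noise drawn per generator call (fixed so that
                     # replicate streams do not depend on batch composition)


def noise_step_scale(settings: SimulationSettings) -> float:
    """Per-step standard deviation of the gating noise kick.

    The published noise amplitude sigma accompanies the parameter tables'
    millisecond time frame, so the Euler-Maruyama kick is
    sigma * sqrt(dt / 1 ms): a diffusion amplitude of sigma per sqrt(ms)
    (~sigma * 31.6 per sqrt(s)).  This reproduces the published
    replicate-to-replicate dispersion (sems of ~0.3 nM and ~0.02 Hz at
    n = 100); a per-sqrt(second) reading gives spreads ~30x smaller.
    """
    return settings.sigma * np.sqrt(settings.dt / 1e-3)

_STATE_NAMES = ("S_E", "S_I", "M_5HT", "conc_5HT")


class SimulationDiverged(RuntimeError):
    """Raised when a state variable becomes non-finite or unbounded."""


@dataclass(frozen=True)
class _Packed:
    """Model parameters as arrays of shape (n_systems, 2); region axis last
    with PFC at index 0 and SCC at index 1."""

    i_thr_e: np.ndarray
    i_thr_i: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    d_e: np.ndarray
    d_i: np.ndarray
    j_nmda: np.ndarray
    j_fb: np.ndarray
    w_plus: np.ndarray
    w_e: np.ndarray
    w_i: np.ndarray
    w5_e: np.ndarray
    w5_i: np.ndarray
    r_dens: np.ndarray
    sign: np.ndarray
    io: np.ndarray
    tau_nmda: np.ndarray
    tau_gaba: np.ndarray
    gamma: np.ndarray
    c_in: np.ndarray
    alpha: np.ndarray
    c_br: np.ndarray
    vmax: np.ndarray
    km: np.ndarray
    tau5: np.ndarray
    j5: np.ndarray
    beta: np.ndarray
    x1: np.ndarray
    x2: np.ndarray


def _pack(params_list: list[ModelParams]) -> _Packed:
    """Stack a list of parameter sets into (n_systems, 2) arrays."""
    cols: dict[str, list[list[float]]] = {f: [] for f in _Packed.__dataclass_fields__}
    for mp in params_list:
        regions = (mp.pfc, mp.scc)
        kins = (mp.kin_pfc, mp.kin_scc)
        factors = [inflammation_factors(mp.inflammation, k) for k in kins]
        cols["i_thr_e"].append([r.I_thr_E for r in regions])
        cols["i_thr_i"].append([r.I_thr_I for r in regions])
        cols["g_e"].append([r.g_E for r in regions])
        cols["g_i"].append([r.g_I for r in regions])
        cols["d_e"].append([r.d_E for r in regions])
        cols["d_i"].append([r.d_I for r in regions])
        cols["j_nmda"].append([r.J_NMDA for r in regions])
        cols["j_fb"].append([r.J for r in regions])
        cols["w_plus"].append([r.w_plus for r in regions])
        cols["w_e"].append([r.W_E for r in regions])
        cols["w_i"].append([r.W_I for r in regions])
        cols["w5_e"].append([r.W5HT_E for r in regions])
        cols["w5_i"].append([r.W5HT_I for r in regions])
        cols["r_dens"].append([r.R for r in regions])
        cols["sign"].append([float(r.serotonergic_sign) for r in regions])
        cols["io"].append([r.Io for r in regions])
        cols["tau_nmda"].append([r.tau_NMDA for r in regions])
        cols["tau_gaba"].append([r.tau_GABA for r in regions])
        cols["gamma"].append([r.gamma for r in regions])
        cols["c_in"].append([r.C_in for r in regions])
        cols["alpha"].append([k.alpha for k in kins])
        cols["c_br"].append([k.C_BR for k in kins])
        cols["vmax"].append([k.Vmax for k in kins])
        cols["km"].append([k.Km for k in kins])
        cols["tau5"].append([k.tau_5HT for k in kins])
        cols["j5"].append([k.J_5HT for k in kins])
        cols["beta"].append([k.beta for k in kins])
        cols["x1"].append([f[0] for f in factors])
        cols["x2"].append([f[1] for f in factors])
    return _Packed(**{k: np.asarray(v, dtype=float) for k, v in cols.items()})


def _rates(pk: _Packed, s_e, s_i, m):
    """Excitatory/inhibitory population rates (Hz) for all systems."""
    sero = pk.sign * pk.r_dens * m
    s_e_other = s_e[:, ::-1]
    i_e = (pk.w_plus * pk.j_nmda * s_e - pk.j_fb * s_i + pk.w5_e * sero
           + pk.w_e * pk.io + pk.j_nmda * pk.c_in * s_e_other)
    i_i = pk.j_nmda * s_e - s_i + pk.w5_i * sero + pk.w_i * pk.io
    r_e = transfer_rate(i_e, pk.g_e, pk.d_e, pk.i_thr_e)
    r_i = transfer_rate(i_i, pk.g_i, pk.d_i, pk.i_thr_i)
    return np.asarray(r_e), np.asarray(r_i)


def _drift(pk: _Packed, s_e, s_i, m, conc):
    """Deterministic drift of all 8 state components; also returns rates."""
    r_e, r_i = _rates(pk, s_e, s_i, m)
    d_se = -s_e / pk.tau_nmda + (1.0 - s_e) * pk.gamma * r_e
    d_si = -s_i / pk.tau_gaba + r_i
    d_m = (-m + pk.j5 / (1.0 + np.exp(-pk.beta * (conc + 1.0)))) / pk.tau5
    d_c = pk.alpha * pk.c_br * r_e * pk.x1 - pk.vmax * conc / (pk.km + conc) * pk.x2
    return d_se, d_si, d_m, d_c, r_e, r_i


def _check_finite(step: int, s_e, s_i, m, conc) -> None:
    for name, arr in zip(_STATE_NAMES, (s_e, s_i, m, conc)):
        if not np.all(np.isfinite(arr)) or np.any(np.abs(arr) > _DIVERGENCE_BOUND):
            bad = int(np.flatnonzero(~np.isfinite(arr).all(axis=-1)
                                     | (np.abs(arr) > _DIVERGENCE_BOUND).any(axis=-1))[0])
            raise SimulationDiverged(
                f"state variable {name} diverged in system {bad} near step {step}")


def _initial_state(rng: np.random.Generator) -> np.ndarray:
    """Random initial condition for one system, shape (4, 2).

    Gating fractions start uniformly in the lower half of their range,
    the serotonergic current anywhere in its range, and serotonin in a
    40-80 nM bracket around the physiological operating point; the 1 s
    discarded transient absorbs the choice.
    """
    s_e = rng.uniform(0.0, 0.5, size=2)
    s_i = rng.uniform(0.0, 0.5, size=2)
    m = rng.uniform(0.0, 1.0, size=2)
    conc = rng.uniform(40.0, 80.0, size=2)
    return np.stack([s_e, s_i, m, conc])


def _integrate(pk: _Packed, rngs: list[np.random.Generator],
               settings: SimulationSettings,
               record_stride: int = 0):
    """Advance all systems for the full duration; return post-transient means.

    Returns (mean_conc, mean_r_e, mean_r_i, final SystemState, trajectory),
    means of shape (n_systems, 2) over exactly the retained steps.  If
    ``record_stride`` > 0, every ``record_stride``-th sample of (conc, r_e)
    is stored and returned as arrays (n_samples, n_systems, 2).
    """
    n_sys = len(rngs)
    dt = settings.dt
    n_steps, n_trans = settings.n_steps, settings.n_transient_steps
    noisy = settings.sigma > 0
    kick = noise_step_scale(settings)

    init = np.stack([_initial_state(r) for r in rngs])  # (n_sys, 4, 2)
    s_e, s_i, m, conc = (init[:, k].copy() for k in range(4))

    sum_c = np.zeros((n_sys, 2))
    sum_re = np.zeros((n_sys, 2))
    sum_ri = np.zeros((n_sys, 2))
    n_ret = 0
    traj_c: list[np.ndarray] = []
    traj_re: list[np.ndarray] = []

    step = 0
    while step < n_steps:
        blk = min(_NOISE_BLOCK, n_steps - step)
        if noisy:
            noise = np.stack([r.standard_normal((blk, 2, 2)) for r in rngs])
        for k in range(blk):
            d_se, d_si, d_m, d_c, r_e, r_i = _drift(pk, s_e, s_i, m, conc)
            if step >= n_trans:
                sum_c += conc
                sum_re += r_e
                sum_ri += r_i
                n_ret += 1
            if record_stride and step % record_stride == 0:
                traj_c.append(conc.copy())
                traj_re.append(r_e.copy())
            s_e += dt * d_se
            s_i += dt * d_si
            if noisy:
                s_e += kick * noise[:, k, :, 0]
                s_i += kick * noise[:, k, :, 1]
            m += dt * d_m
            conc += dt * d_c
            np.clip(s_e, 0.0, 1.0, out=s_e)
            np.clip(s_i, 0.0, None, out=s_i)
            np.clip(conc, 0.0, None, out=conc)
            step += 1
        _check_finite(step, s_e, s_i, m, conc)

    final = SystemState(s_e, s_i, m, conc, time=n_steps * dt)
    traj = (np.array(traj_c), np.array(traj_re)) if record_stride else None
    return sum_c / n_ret, sum_re / n_ret, sum_ri / n_ret, final, traj


def _replicate_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed))


def euler_maruyama_step(state: SystemState, params: ModelParams,
                        settings: SimulationSettings,
                        noise_draws: np.ndarray) -> SystemState:
    """One Euler-Maruyama step of the full coupled system.

    ``state`` holds arrays of shape (2,) (region axis); ``noise_draws`` are
    4 independent standard normal values, shape (2, 2): region x (E, I).
    Gating variables get drift * dt plus the scaled noise kick (see
    :func:`noise_step_scale`); M and the serotonin concentration advance by
    the deterministic Euler update.  Clamps (S_E in [0,1]; S_I, conc >= 0)
    apply after the step.
    """
    pk = _pack([params])
    s_e = np.atleast_2d(np.asarray(state.S_E, dtype=float))
    s_i = np.atleast_2d(np.asarray(state.S_I, dtype=float))
    m = np.atleast_2d(np.asarray(state.M_5HT, dtype=float))
    conc = np.atleast_2d(np.asarray(state.conc_5HT, dtype=float))
    noise = np.asarray(noise_draws, dtype=float).reshape(1, 2, 2)
    dt = settings.dt
    d_se, d_si, d_m, d_c, _, _ = _drift(pk, s_e, s_i, m, conc)
    kick = noise_step_scale(settings)
    s_e = np.clip(s_e + dt * d_se + kick * noise[:, :, 0], 0.0, 1.0)
    s_i = np.clip(s_i + dt * d_si + kick * noise[:, :, 1], 0.0, None)
    m = m + dt * d_m
    conc = np.clip(conc + dt * d_c, 0.0, None)
    for name, arr in zip(_STATE_NAMES, (s_e, s_i, m, conc)):
        if not np.all(np.isfinite(arr)):
            raise SimulationDiverged(f"state variable {name} became non-finite")
    return SystemState(s_e[0], s_i[0], m[0], conc[0], time=state.time + dt)


@dataclass(frozen=True)
class TrajectorySummary:
    """Post-transient time averages of one stochastic run (region axis:
    PFC=0, SCC=1)."""

    serotonin: np.ndarray   # nM, shape (2,)
    rate_E: np.ndarray      # Hz, shape (2,)
    rate_I: np.ndarray      # Hz, shape (2,)
    n_steps: int
    n_retained: int
    seed: int
    final_state: SystemState
    trajectory: tuple[np.ndarray, np.ndarray] | None = None


@dataclass(frozen=True)
class ConditionSummary:
    """Replicate mean and standard error per region and observable."""

    serotonin_mean: np.ndarray
    serotonin_sem: np.ndarray
    rate_E_mean: np.ndarray
    rate_E_sem: np.ndarray
    rate_I_mean: np.ndarray
    rate_I_sem: np.ndarray
    n_reps: int
    base_seed: int
    meta: dict = field(default_factory=dict)


def run_trajectory(params: ModelParams, settings: SimulationSettings,
                   seed: int, record_stride: int = 0) -> TrajectorySummary:
    """Integrate one replicate from a random initial condition.

    Runs ``duration``/``dt`` Euler-Maruyama steps, discards the initial
    transient, and returns the time-averaged post-transient serotonin
    concentration and population rates per region.
    """
    pk = _pack([params])
    mc, mre, mri, final, traj = _integrate(pk, [_replicate_rng(seed)], settings,
                                           record_stride=record_stride)
    return TrajectorySummary(
        serotonin=mc[0], rate_E=mre[0], rate_I=mri[0],
        n_steps=settings.n_steps,
        n_retained=settings.n_retained_steps,
        seed=seed, final_state=SystemState(final.S_E[0], final.S_I[0],
                                           final.M_5HT[0], final.conc_5HT[0],
                                           final.time),
        trajectory=traj)


def _sem(values: np.ndarray) -> np.ndarray:
    if values.shape[0] < 2:
        return np.zeros(values.shape[1:])
    return values.std(axis=0, ddof=1) / np.sqrt(values.shape[0])


def summarize_replicates(mc: np.ndarray, mre: np.ndarray, mri: np.ndarray,
                         settings: SimulationSettings,
                         meta: dict | None = None) -> ConditionSummary:
    return ConditionSummary(
        serotonin_mean=mc.mean(axis=0), serotonin_sem=_sem(mc),
        rate_E_mean=mre.mean(axis=0), rate_E_sem=_sem(mre),
        rate_I_mean=mri.mean(axis=0), rate_I_sem=_sem(mri),
        n_reps=mc.shape[0], base_seed=settings.base_seed,
        meta=meta or {})


def run_replicates(params: ModelParams, settings: SimulationSettings,
                   meta: dict | None = None) -> ConditionSummary:
    """Run ``n_reps`` independent replicates and aggregate mean and sem.

    Replicate r uses the counter-based stream keyed by base_seed + r, so the
    summary is reproducible given the base seed and each replicate matches a
    standalone :func:`run_trajectory` call with the same seed.
    """
    pk_one = _pack([params])
    pk = _Packed(**{f: np.repeat(getattr(pk_one, f), settings.n_reps, axis=0)
                    for f in _Packed.__dataclass_fields__})
    rngs = [_replicate_rng(settings.base_seed + r) for r in range(settings.n_reps)]
    try:
        mc, mre, mri, _, _ = _integrate(pk, rngs, settings)
    except SimulationDiverged as err:
        raise SimulationDiverged(f"{err} (replicate index = system index)") from err
    return summarize_replicates(mc, mre, mri, settings, meta)


def run_conditions_batch(params_list: list[ModelParams],
                         settings: SimulationSettings,
                         metas: list[dict] | None = None
                         ) -> list[ConditionSummary]:
    """Run many conditions x n_reps replicates in one vectorized batch.

    Equivalent to calling :func:`run_replicates` per condition (identical
    replicate streams) but advances all systems together, which keeps a
    full condition grid fast on one core.
    """
    n_rep = settings.n_reps
    pks = [_pack([p]) for p in params_list]
    pk = _Packed(**{f: np.repeat(np.concatenate([getattr(p, f) for p in pks]),
                                 n_rep, axis=0)
                    for f in _Packed.__dataclass_fields__})
    rngs = [_replicate_rng(settings.base_seed + r)
            for _ in params_list for r in range(n_rep)]
    mc, mre, mri, _, _ = _integrate(pk, rngs, settings)
    out = []
    for i in range(len(params_list)):
        sl = slice(i * n_rep, (i + 1) * n_rep)
        meta = metas[i] if metas else None
        out.append(summarize_replicates(mc[sl], mre[sl], mri[sl], settings, meta))
    return out


# ---------------------------------------------------------------------------
# Deterministic fixed point
# ---------------------------------------------------------------------------

def _oracle_initial(pk: _Packed, n_sys: int) -> tuple[np.ndarray, ...]:
    s_e = np.full((n_sys, 2), 0.2)
    s_i = np.full((n_sys, 2), 0.1)
    m = np.full((n_sys, 2), 0.6)
    conc = np.full((n_sys, 2), 60.0)
    return s_e, s_i, m, conc


def steady_state_oracle(params: ModelParams, tol: float = 1e-10,
                        relax_time: float = 20.0) -> SystemState:
    """Noise-free fixed point of the full coupled 8-dimensional system.

    Relaxes the deterministic dynamics toward the attractor, then polishes
    with a root-finder on the drift.  Returns a state whose drift components
    are all below ``tol`` in absolute value; raises if the residual cannot
    be driven below ``tol``.
    """
    state = steady_state_oracle_batch([params], tol=tol, relax_time=relax_time)
    return SystemState(state.S_E[0], state.S_I[0], state.M_5HT[0],
                       state.conc_5HT[0], state.time)


def steady_state_oracle_batch(params_list: list[ModelParams],
                              tol: float = 1e-10,
                              relax_time: float = 20.0) -> SystemState:
    """Vectorized :func:`steady_state_oracle` over many conditions."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    pk = _pack(params_list)
    n_sys = len(params_list)
    s_e, s_i, m, conc = _oracle_initial(pk, n_sys)
    # coarse deterministic relaxation (the attractor is stable); a larger
    # step than the stochastic dt is fine here
    dt = 5e-4
    for _ in range(int(relax_time / dt)):
        d_se, d_si, d_m, d_c, _, _ = _drift(pk, s_e, s_i, m, conc)
        s_e += dt * d_se
        s_i += dt * d_si
        m += dt * d_m
        conc += dt * d_c

    # per-system Newton/hybrid polish on the 8-dim drift
    for i in range(n_sys):
        pk_i = _Packed(**{f: getattr(pk, f)[i:i + 1]
                          for f in _Packed.__dataclass_fields__})

        def fun(x: np.ndarray) -> np.ndarray:
            xs = x.reshape(4, 1, 2)
            d = _drift(pk_i, xs[0], xs[1], xs[2], xs[3])
            return np.concatenate([c.ravel() for c in d[:4]])

        x0 = np.concatenate([s_e[i], s_i[i], m[i], conc[i]])
        sol = scipy.optimize.root(fun, x0, method="hybr", tol=1e-13)
        res = np.max(np.abs(fun(sol.x)))
        if res >= tol:
            raise RuntimeError(
                f"fixed point did not converge for system {i}: "
                f"max |drift| = {res:.3e} >= tol {tol:.3e}")
        s_e[i], s_i[i], m[i], conc[i] = sol.x.reshape(4, 2)
    return SystemState(s_e, s_i, m, conc, time=np.inf)


def oracle_rates(params: ModelParams, state: SystemState
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Population rates (r_E, r_I) per region at a given (fixed-point) state."""
    pk = _pack([params])
    r_e, r_i = _rates(pk, np.atleast_2d(state.S_E), np.atleast_2d(state.S_I),
                      np.atleast_2d(state.M_5HT))
    return r_e[0], r_i[0]
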