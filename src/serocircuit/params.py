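"""Parameter containers and config I/O for the cingulo-frontal circuit model.

The model couples two cortical regions — prefrontal cortex (PFC) and
subcallosal cingulate cortex (SCC) — each a reduced excitatory/inhibitory
neural mass driven by NMDA, GABA and serotonergic currents.  Extracellular
serotonin follows synthesis/reuptake (Michaelis-Menten) kinetics modulated
by a cytokine "degree of inflammation" (fold-elevation of TNFα over basal).

All internal quantities use one consistent unit frame: time in seconds,
rates in Hz, currents in nA, concentrations in nM.  Published parameter
tables mix ms and s conventions (e.g. synaptic time constants in ms and the
NMDA kinetic parameter γ quoted per-ms); the config loader converts, so
that e.g. the excitatory gating fixed point is S_E* = γτr/(1+γτr) with
τ_NMDA = 0.1 s and γ = 0.641.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

PFC = "PFC"
SCC = "SCC"
REGIONS = (PFC, SCC)

#: Degree-of-inflammation levels: fold-elevation of TNFα over basal.
DEGREE_LEVELS = {
    "control": 1.0,
    "mild": 1.25,
    "moderate": 1.4,
    "severe": 2.3,
}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class NeuralRegionParams:
    """Neural-mass parameters of one cortical region.

    ``serotonergic_sign`` is +1 for the PFC (excitatory 5HT2A receptors
    dominate) and -1 for the SCC (inhibitory 5HT1A receptors dominate):
    the serotonergic current adds to PFC input currents and subtracts from
    SCC input currents.  ``C_in`` scales the long-range NMDA input from
    the other region (SCC→PFC: 0.01; PFC→SCC: 0.005), multiplied by the
    receiving region's ``J_NMDA``.
    """

    region_label: str
    I_thr_E: float = 0.4       # nA
    I_thr_I: float = 0.286     # nA
    g_E: float = 310.0         # nC^-1
    g_I: float = 615.0         # nC^-1
    d_E: float = 0.16          # dimensionless
    d_I: float = 0.087         # dimensionless
    J_NMDA: float = 0.15       # nA
    J: float = 1.135           # dimensionless
    w_plus: float = 1.4        # recurrent excitation weight
    W_E: float = 1.0           # external-input weight, E population
    W_I: float = 0.7           # external-input weight, I population
    W5HT_E: float = 0.48       # serotonergic weight onto E population
    W5HT_I: float = 0.47       # serotonergic weight onto I population
    R: float = 0.6             # serotonergic receptor density
    serotonergic_sign: int = 1
    Io: float = 0.32           # nA
    tau_NMDA: float = 0.1      # s
    tau_GABA: float = 0.01     # s
    gamma: float = 0.641       # NMDA kinetic parameter (s-frame)
    C_in: float = 0.01         # incoming long-range coupling constant

    def __post_init__(self) -> None:
        _require(self.region_label in REGIONS, f"unknown region {self.region_label!r}")
        _require(self.serotonergic_sign in (1, -1), "serotonergic_sign must be +1 or -1")
        _require(
            (self.serotonergic_sign == 1) == (self.region_label == PFC),
            "serotonergic_sign must be +1 iff region is PFC",
        )
        for name in ("I_thr_E", "I_thr_I", "g_E", "g_I", "d_E", "d_I", "J_NMDA",
                     "J", "w_plus", "W_E", "W_I", "R", "Io", "tau_NMDA",
                     "tau_GABA", "gamma"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        # Serotonergic weights and long-range coupling may be zeroed to
        # decouple the region (used by fixed-point cross-checks).
        for name in ("W5HT_E", "W5HT_I", "C_in"):
            _require(getattr(self, name) >= 0, f"{name} must be nonnegative")


@dataclass(frozen=True)
class SerotoninKineticsParams:
    """Serotonin synthesis/reuptake and serotonergic-current parameters.

    Synthesis is ``alpha * C_BR * r_E`` (linear in excitatory rate, scaled
    by raphe fiber density ``C_BR``); reuptake is Michaelis-Menten with
    ``Vmax`` (nM/s) and ``Km`` (nM).  ``c1``/``m`` shape the inflammatory
    suppression of synthesis (X1); ``c2`` the inflammatory increase of
    reuptake (X2).  ``tau_5HT``, ``J_5HT``, ``beta`` set the time constant,
    range and slope of the sigmoidal serotonergic current.
    """

    alpha: float = 5.0
    C_BR: float = 15.0
    Vmax: float = 1300.0       # nM/s
    Km: float = 170.0          # nM
    tau_5HT: float = 0.12      # s
    J_5HT: float = 1.0
    beta: float = 0.008        # nM^-1
    c1: float = 5.0
    m: float = 2.0
    c2: float = 0.019

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be strictly positive")


@dataclass(frozen=True)
class InflammationCondition:
    """Cytokine state: degree of inflammation and anti-inflammatory blocker.

    ``degree`` is the TNFα fold-elevation [Cyt]/[Cyt]b (1 = control).  The
    Heaviside gate on cytokine excess is 0 for degree <= 1, so the control
    condition leaves synthesis/reuptake unmodified.  ``B`` in (0, 1] scales
    the cytokine term (B = 1: untreated; B = 0.55: anti-inflammatory drug).
    """

    degree: float = 1.0
    B: float = 1.0
    cyt: float | None = None      # pg/mL, optional provenance
    cyt_b: float | None = None    # pg/mL

    def __post_init__(self) -> None:
        _require(self.degree >= 0, "degree of inflammation must be >= 0")
        _require(0 < self.B <= 1, "blocker factor B must lie in (0, 1]")

    @classmethod
    def from_concentrations(cls, cyt: float, cyt_b: float, B: float = 1.0
                            ) -> "InflammationCondition":
        from .interventions import degree_of_inflammation
        return cls(degree=degree_of_inflammation(cyt, cyt_b), B=B,
                   cyt=cyt, cyt_b=cyt_b)


def _default_pfc() -> NeuralRegionParams:
    return NeuralRegionParams(region_label=PFC)


def _default_scc() -> NeuralRegionParams:
    return NeuralRegionParams(
        region_label=SCC, J_NMDA=0.33, W_I=0.8, W5HT_E=0.19, W5HT_I=0.19,
        Io=0.45, serotonergic_sign=-1, C_in=0.005,
    )


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the coupled two-region model.

    Serotonin kinetics are held per region because the synthesis-shape
    parameter c1 differs (PFC: 5, SCC: 4); Km and the Michaelis-Menten
    machinery are shared values edited jointly by treatments.
    """

    pfc: NeuralRegionParams = field(default_factory=_default_pfc)
    scc: NeuralRegionParams = field(default_factory=_default_scc)
    kin_pfc: SerotoninKineticsParams = field(default_factory=SerotoninKineticsParams)
    kin_scc: SerotoninKineticsParams = field(
        default_factory=lambda: SerotoninKineticsParams(c1=4.0))
    inflammation: InflammationCondition = field(default_factory=InflammationCondition)

    def region(self, label: str) -> NeuralRegionParams:
        return self.pfc if label == PFC else self.scc

    def kinetics(self, label: str) -> SerotoninKineticsParams:
        return self.kin_pfc if label == PFC else self.kin_scc

    def replace(self, **kwargs: Any) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SimulationSettings:
    """Integration protocol for the stochastic simulation.

    Defaults follow the published protocol: Euler-Maruyama with dt = 0.1 ms,
    7 s of model time per run, the first 1 s discarded as transient, gating
    noise amplitude sigma = 0.01 (quoted per sqrt-millisecond, matching the
    parameter tables' ms frame), and 100 replicates per condition.
    """

    dt: float = 1e-4          # s
    duration: float = 7.0     # s
    transient: float = 1.0    # s
    sigma: float = 0.01       # nA
    n_reps: int = 100
    base_seed: int = 2024

    def __post_init__(self) -> None:
        _require(0 < self.dt <= self.transient < self.duration,
                 "need 0 < dt <= transient < duration")
        _require(self.sigma >= 0, "sigma must be >= 0")
        _require(self.n_reps >= 1, "n_reps must be >= 1")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    @property
    def n_transient_steps(self) -> int:
        return round(self.transient / self.dt)

    @property
    def n_retained_steps(self) -> int:
        return self.n_steps - self.n_transient_steps


# ---------------------------------------------------------------------------
# Config I/O (printed-unit YAML <-> internal-unit dataclasses)
# ---------------------------------------------------------------------------

_REGION_KEYS = {
    "I_thr_E": "i_thr_e_na", "I_thr_I": "i_thr_i_na", "g_E": "g_e",
    "g_I": "g_i", "d_E": "d_e", "d_I": "d_i", "J_NMDA": "j_nmda_na",
    "J": "j", "w_plus": "w_plus", "W_E": "w_e", "W_I": "w_i",
    "W5HT_E": "w_5ht_e", "W5HT_I": "w_5ht_i", "R": "r_density",
    "Io": "io_na", "C_in": "c_in",
}


def _region_to_dict(p: NeuralRegionParams) -> dict[str, Any]:
    d = {yk: getattr(p, ak) for ak, yk in _REGION_KEYS.items()}
    d["tau_nmda_ms"] = p.tau_NMDA * 1e3
    d["tau_gaba_ms"] = p.tau_GABA * 1e3
    d["gamma_per_ms"] = p.gamma * 1e-3
    return d


def _region_from_dict(label: str, d: dict[str, Any]) -> NeuralRegionParams:
    kwargs: dict[str, Any] = {ak: float(d[yk]) for ak, yk in _REGION_KEYS.items()}
    kwargs["tau_NMDA"] = float(d["tau_nmda_ms"]) * 1e-3
    kwargs["tau_GABA"] = float(d["tau_gaba_ms"]) * 1e-3
    kwargs["gamma"] = float(d["gamma_per_ms"]) * 1e3
    kwargs["serotonergic_sign"] = 1 if label == PFC else -1
    return NeuralRegionParams(region_label=label, **kwargs)


def params_to_dict(params: ModelParams, settings: SimulationSettings | None = None
                   ) -> dict[str, Any]:
    """Serialize to a plain dict in printed units (ms, per-ms γ)."""
    ser: dict[str, Any] = {
        "alpha": params.kin_pfc.alpha,
        "c_br": params.kin_pfc.C_BR,
        "vmax_nm_per_s": params.kin_pfc.Vmax,
        "km_nm": params.kin_pfc.Km,
        "tau_5ht_ms": params.kin_pfc.tau_5HT * 1e3,
        "j_5ht": params.kin_pfc.J_5HT,
        "beta_per_nm": params.kin_pfc.beta,
        "c1": {"pfc": params.kin_pfc.c1, "scc": params.kin_scc.c1},
        "m": params.kin_pfc.m,
        "c2": params.kin_pfc.c2,
    }
    out: dict[str, Any] = {
        "pfc": _region_to_dict(params.pfc),
        "scc": _region_to_dict(params.scc),
        "serotonin": ser,
        "inflammation": {"degree": params.inflammation.degree,
                         "B": params.inflammation.B},
    }
    if settings is not None:
        out["simulation"] = {
            "dt_ms": settings.dt * 1e3, "duration_s": settings.duration,
            "transient_s": settings.transient, "sigma": settings.sigma,
            "n_reps": settings.n_reps, "base_seed": settings.base_seed,
        }
    return out


def params_from_dict(d: dict[str, Any]) -> tuple[ModelParams, SimulationSettings]:
    ser = d["serotonin"]
    shared = dict(
        alpha=float(ser["alpha"]), C_BR=float(ser["c_br"]),
        Vmax=float(ser["vmax_nm_per_s"]), Km=float(ser["km_nm"]),
        tau_5HT=float(ser["tau_5ht_ms"]) * 1e-3, J_5HT=float(ser["j_5ht"]),
        beta=float(ser["beta_per_nm"]), m=float(ser["m"]), c2=float(ser["c2"]),
    )
    infl = d.get("inflammation", {})
    params = ModelParams(
        pfc=_region_from_dict(PFC, d["pfc"]),
        scc=_region_from_dict(SCC, d["scc"]),
        kin_pfc=SerotoninKineticsParams(c1=float(ser["c1"]["pfc"]), **shared),
        kin_scc=SerotoninKineticsParams(c1=float(ser["c1"]["scc"]), **shared),
        inflammation=InflammationCondition(degree=float(infl.get("degree", 1.0)),
                                           B=float(infl.get("B", 1.0))),
    )
    sim = d.get("simulation", {})
    settings = SimulationSettings(
        dt=float(sim.get("dt_ms", 0.1)) * 1e-3,
        duration=float(sim.get("duration_s", 7.0)),
        transient=float(sim.get("transient_s", 1.0)),
        sigma=float(sim.get("sigma", 0.01)),
        n_reps=int(sim.get("n_reps", 100)),
        base_seed=int(sim.get("base_seed", 2024)),
    )
    return params, settings


def save_config(path: str, params: ModelParams,
                settings: SimulationSettings | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params, settings), fh, sort_keys=False)


def load_config(path: str) -> tuple[ModelParams, SimulationSettings]:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def default_config_path() -> str:
    """Path of the shipped default-parameter YAML (printed units)."""
    return str(resources.files("serocircuit.data") / "default_params.yaml")


def load_default_params() -> tuple[ModelParams, SimulationSettings]:
    return load_config(default_config_path())
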