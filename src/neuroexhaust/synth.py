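"""Synthetic-data generators with planted ground truth.

Everything the analysis pipeline consumes can be generated here:

* conductance-model neurons under current-clamp step protocols (the
  2-s, 5-pA, -20..+60 pA standard) and voltage-clamp step protocols
  (1-s steps, -80..+60 mV from -80 mV holding),
* 120-s gap-free spontaneous EPSC traces at -80 mV holding,
* single-turn [U-13C]glutamine isotopologue panels with a tunable
  reductive-flux fraction.

The neuron model plants an "exhaustion" mechanism: a sodium-availability
scale ``rho`` in [0, 1] and a slow availability gate whose recovery time
constant ``tau_s`` is long at rest. Archetypes span the firing classes:
T1 (non-firing, rho = 0.05), T2 (single spike, rho = 0.25), T3-control
(repetitive, rho = 1.0) and T3-patient (repetitive but attenuating,
rho = 0.35). All constants are stand-ins chosen so the archetypes express
these phenotypes; none is an estimate fitted to any real cell.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import _hh
from .trace_io import ClampMode, ProtocolDescriptor, SweepRecording, build_step_protocol
from .waveforms import biexp_kernel

__all__ = [
    "NeuronParams",
    "ArchetypeSpec",
    "CohortPlan",
    "EPSCPlan",
    "TracingPlan",
    "ARCHETYPES",
    "default_cc_protocol",
    "default_vc_protocol",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "simulate_epsc_trace",
    "simulate_test_pulse",
    "generate_cohort",
    "generate_mid_panel",
    "single_turn_mid",
    "METABOLITE_CARBONS",
]


@dataclass(frozen=True)
class NeuronParams:
    """Single-compartment conductance-model parameters.

    Units: pF, nS, mV, ms, pA. ``rho`` scales sodium availability
    (patient-like < 1); the slow gate s has steady state
    ``1/(1+exp((V-v_s)/k_s))``, fast entry time constant ``tau_s_entry``
    at depolarised potentials and slow recovery ``tau_s`` at rest.
    """

    c_m: float = 30.0          # pF
    g_na: float = 4000.0       # nS (maximal, scaled by rho)
    rho: float = 1.0           # sodium availability in [0, 1]
    g_k: float = 270.0         # nS
    g_l: float = 3.0           # nS
    e_na: float = 55.0         # mV
    e_k: float = -90.0         # mV
    e_l: float = -65.0         # mV
    v_shift: float = -56.0     # shift of the classic rate functions
    v_s: float = -35.0         # slow-gate half-availability voltage, mV
    k_s: float = 4.0           # slow-gate slope, mV
    tau_s: float = 2000.0      # slow-gate recovery time constant, ms
    tau_s_entry: float = 300.0  # slow-gate entry time constant, ms
    noise_sigma: float = 0.0   # additive current noise, pA
    rate_scale: float = 5.0    # temperature-like factor on the h and n rates

    def __post_init__(self) -> None:
        for name in ("c_m", "g_na", "g_k", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.tau_s <= 0 or self.tau_s_entry <= 0 or self.k_s <= 0:
            raise ValueError("tau_s, tau_s_entry and k_s must be > 0")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.c_m, self.g_na, self.rho, self.g_k, self.g_l,
             self.e_na, self.e_k, self.e_l, self.v_shift,
             self.v_s, self.k_s, self.tau_s, self.tau_s_entry,
             self.noise_sigma, self.rate_scale],
            dtype=np.float64,
        )


#: Archetype parameter sets expressing the three firing classes plus the
#: attenuating patient-like multi-spiker. rho ordering (1.0 / 0.35 / 0.25 /
#: 0.05) mirrors the qualitative control-vs-patient severity axis.
ARCHETYPES: dict[str, NeuronParams] = {
    "T3-control": NeuronParams(rho=1.0),
    # patient-like: reduced availability plus a depolarised-shifted,
    # shallower slow-inactivation curve (partly unavailable even at rest)
    "T3-patient": NeuronParams(rho=0.35, v_s=-57.0, k_s=10.0,
                               tau_s_entry=150.0),
    # weak delayed rectifier: one spike then depolarisation block
    "T2": NeuronParams(rho=0.25, g_k=60.0),
    "T1": NeuronParams(rho=0.05),
}


def default_cc_protocol(sampling_rate: float = 20_000.0) -> ProtocolDescriptor:
    """2-s current steps of 5 pA from -20 to +60 pA (17 sweeps)."""
    return build_step_protocol(-20.0, 60.0, 5.0, step_duration=2.0,
                               pre_duration=0.25, post_duration=0.25,
                               sampling_rate=sampling_rate,
                               mode=ClampMode.CURRENT_CLAMP, holding_level=0.0)


def default_vc_protocol(sampling_rate: float = 20_000.0) -> ProtocolDescriptor:
    """1-s voltage steps of 10 mV, -80 to +60 mV, from -80 mV holding."""
    return build_step_protocol(-80.0, 60.0, 10.0, step_duration=1.0,
                               pre_duration=0.25, post_duration=0.25,
                               sampling_rate=sampling_rate,
                               mode=ClampMode.VOLTAGE_CLAMP, holding_level=-80.0)


def _record_every(protocol: ProtocolDescriptor, dt_ms: float) -> int:
    period_ms = 1000.0 / protocol.sampling_rate
    ratio = period_ms / dt_ms
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(
            f"integration step {dt_ms} ms must divide the sampling period "
            f"{period_ms} ms"
        )
    return int(round(ratio))


def _check_dt(dt_ms: float) -> None:
    if dt_ms > 0.05:
        raise ValueError("dt must be <= 0.05 ms for a stable fixed-step solve")


def simulate_current_clamp(
    params: NeuronParams,
    protocol: ProtocolDescriptor | None = None,
    dt_ms: float = 0.01,
    seed: int = 0,
    cell_id: str = "sim",
    genotype: str = "control",
    settle_ms: float = 300.0,
) -> SweepRecording:
    """Simulate a step-current-injection sweep set (one sweep per level).

    The model is settled at the holding current before each sweep. The
    returned recording embeds ground truth in ``metadata['truth']``:
    per-sweep spike counts from the integrator's threshold-crossing log
    and the exact parameters used.
    """
    _check_dt(dt_ms)
    protocol = protocol or default_cc_protocol()
    if protocol.mode is not ClampMode.CURRENT_CLAMP:
        raise ValueError("protocol mode must be current_clamp")
    rec_every = _record_every(protocol, dt_ms)
    p = params.to_vector()
    n_pre = int(round(protocol.pre_duration * 1000.0 / dt_ms))
    n_step = int(round(protocol.step_duration * 1000.0 / dt_ms))
    n_post = int(round(protocol.post_duration * 1000.0 / dt_ms))
    n_settle = int(round(settle_ms / dt_ms))
    sweeps, counts = [], []
    for i, level in enumerate(protocol.step_levels):
        sweep_seed = (int(seed) * 100_003 + 7919 * i) % (2**31 - 1)
        v, n_spk, ok = _hh.integrate_cc_sweep(
            p, float(protocol.holding_level), float(level),
            n_pre, n_step, n_post, n_settle, dt_ms, rec_every, sweep_seed)
        if not ok:
            raise RuntimeError(
                f"integration unstable at step {level} pA; use a smaller dt "
                f"(got dt={dt_ms} ms)")
        sweeps.append(v)
        counts.append(int(n_spk))
    return SweepRecording(
        cell_id=cell_id, protocol=protocol, sweeps=sweeps, genotype=genotype,
        capacitance_pf=params.c_m,
        metadata={"truth": {"spike_counts": counts, "params": asdict(params),
                            "seed": int(seed)}},
    )


def simulate_voltage_clamp(
    params: NeuronParams,
    protocol: ProtocolDescriptor | None = None,
    dt_ms: float = 0.01,
    cell_id: str = "sim",
    genotype: str = "control",
) -> SweepRecording:
    """Simulate a voltage-step sweep set; currents in pA.

    V is clamped to the command; gating ODEs are advanced with their exact
    exponential update at fixed V. Ground-truth per-step peak inward
    (baseline-subtracted) currents are embedded in the metadata.
    """
    _check_dt(dt_ms)
    protocol = protocol or default_vc_protocol()
    if protocol.mode is not ClampMode.VOLTAGE_CLAMP:
        raise ValueError("protocol mode must be voltage_clamp")
    rec_every = _record_every(protocol, dt_ms)
    p = params.to_vector()
    n_pre = int(round(protocol.pre_duration * 1000.0 / dt_ms))
    n_step = int(round(protocol.step_duration * 1000.0 / dt_ms))
    n_post = int(round(protocol.post_duration * 1000.0 / dt_ms))
    sweeps, peaks = [], []
    for level in protocol.step_levels:
        i_trace, peak, ok = _hh.integrate_vc_sweep(
            p, float(protocol.holding_level), float(level),
            n_pre, n_step, n_post, dt_ms, rec_every)
        if not ok:
            raise RuntimeError("integration produced non-finite currents; "
                               "use a smaller dt")
        sweeps.append(i_trace)
        peaks.append(float(peak))
    return SweepRecording(
        cell_id=cell_id, protocol=protocol, sweeps=sweeps, genotype=genotype,
        capacitance_pf=params.c_m,
        metadata={"truth": {"peak_inward_pa": peaks, "params": asdict(params)}},
    )


# ---------------------------------------------------------------------------
# spontaneous EPSCs


@dataclass(frozen=True)
class EPSCPlan:
    """Plan for a gap-free spontaneous-EPSC recording at -80 mV holding.

    Events are a Poisson process at ``rate_hz``; waveforms are
    peak-normalised biexponentials (tau_decay > tau_rise) scaled by
    lognormal amplitudes with mean ``amp_mean_pa`` and log-sd
    ``amp_sigma_ln``. The narrow default spread keeps the planted
    signal-to-noise ratio (amp_mean_pa / noise_sigma_pa) representative of
    every event. Inward currents are negative.
    """

    duration_s: float = 120.0
    rate_hz: float = 1.0
    amp_mean_pa: float = 50.0
    amp_sigma_ln: float = 0.12
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 10.0
    noise_sigma_pa: float = 2.0
    sampling_rate: float = 20_000.0
    holding_mv: float = -80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau_decay_ms > self.tau_rise_ms > 0:
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.rate_hz < 0:
            raise ValueError("rate must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")


def simulate_epsc_trace(plan: EPSCPlan) -> tuple[SweepRecording, pd.DataFrame]:
    """Generate a gap-free EPSC trace plus its ground-truth event list.

    Returns ``(recording, truth)`` where truth has columns ``onset_s`` and
    ``amplitude_pa`` (positive magnitudes; the trace deflections are
    negative).
    """
    rng = np.random.default_rng(plan.seed)
    n_samples = int(round(plan.duration_s * plan.sampling_rate))
    n_events = rng.poisson(plan.rate_hz * plan.duration_s)
    onsets = np.sort(rng.uniform(0.0, plan.duration_s, size=n_events))
    mu = np.log(plan.amp_mean_pa) - 0.5 * plan.amp_sigma_ln**2
    amps = rng.lognormal(mu, plan.amp_sigma_ln, size=n_events)
    trace = np.zeros(n_samples)
    # kernel truncated at 10 decay constants (residual < 5e-5 of peak)
    klen = int(round(10.0 * plan.tau_decay_ms * 1e-3 * plan.sampling_rate))
    t_k = np.arange(klen) / plan.sampling_rate * 1000.0  # ms
    kernel = biexp_kernel(t_k, plan.tau_rise_ms, plan.tau_decay_ms)
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * plan.sampling_rate))
        seg = min(klen, n_samples - i0)
        if seg > 0:
            trace[i0:i0 + seg] -= amp * kernel[:seg]
    if plan.noise_sigma_pa > 0:
        trace += rng.normal(0.0, plan.noise_sigma_pa, size=n_samples)
    protocol = ProtocolDescriptor(
        mode=ClampMode.GAP_FREE, holding_level=plan.holding_mv,
        step_levels=(), step_duration=plan.duration_s,
        pre_duration=0.0, post_duration=0.0,
        sampling_rate=plan.sampling_rate)
    truth = pd.DataFrame({"onset_s": onsets, "amplitude_pa": amps})
    rec = SweepRecording(
        cell_id="epsc-sim", protocol=protocol, sweeps=[trace],
        metadata={"truth": {"n_events": int(n_events), "plan": asdict(plan)}})
    return rec, truth


def simulate_test_pulse(
    r_series_mohm: float,
    c_pf: float,
    dv_mv: float = -5.0,
    r_membrane_mohm: float = np.inf,
    holding_mv: float = -80.0,
    pre_s: float = 0.05,
    pulse_s: float = 0.1,
    post_s: float = 0.05,
    sampling_rate: float = 50_000.0,
    noise_sigma_pa: float = 0.0,
    seed: int = 0,
) -> SweepRecording:
    """Analytic RC response to a voltage-clamp test pulse (for capacitance
    estimation): current transient ``(dV/Rs) exp(-t/tau)`` decaying to the
    steady current through the series+membrane path."""
    if r_series_mohm <= 0 or c_pf <= 0:
        raise ValueError("R and C must be positive")
    n_pre = int(round(pre_s * sampling_rate))
    n_pulse = int(round(pulse_s * sampling_rate))
    n_post = int(round(post_s * sampling_rate))
    if np.isinf(r_membrane_mohm):
        steady_na = 0.0
        tau_ms = r_series_mohm * c_pf * 1e-3
    else:
        steady_na = dv_mv / (r_series_mohm + r_membrane_mohm)
        r_par = r_series_mohm * r_membrane_mohm / (r_series_mohm + r_membrane_mohm)
        tau_ms = r_par * c_pf * 1e-3
    peak_na = dv_mv / r_series_mohm
    t_ms = np.arange(n_pulse) / sampling_rate * 1000.0
    on = steady_na + (peak_na - steady_na) * np.exp(-t_ms / tau_ms)
    off = -(peak_na - steady_na) * np.exp(-np.arange(n_post) / sampling_rate
                                          * 1000.0 / tau_ms)
    trace_pa = 1000.0 * np.concatenate([np.zeros(n_pre), on, off])
    if noise_sigma_pa > 0:
        rng = np.random.default_rng(seed)
        trace_pa = trace_pa + rng.normal(0, noise_sigma_pa, trace_pa.size)
    protocol = ProtocolDescriptor(
        mode=ClampMode.VOLTAGE_CLAMP, holding_level=holding_mv,
        step_levels=(holding_mv + dv_mv,), step_duration=pulse_s,
        pre_duration=pre_s, post_duration=post_s, sampling_rate=sampling_rate)
    return SweepRecording(
        cell_id="test-pulse", protocol=protocol, sweeps=[trace_pa],
        metadata={"truth": {"r_series_mohm": r_series_mohm, "c_pf": c_pf,
                            "dv_mv": dv_mv}})


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class ArchetypeSpec:
    """One archetype in a cohort plan: label, mean parameters, relative
    jitter (fractional sd of a multiplicative perturbation) and count."""

    label: str
    params: NeuronParams
    count: int
    jitter: float = 0.05
    genotype: str = "control"

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError("count must be > 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class CohortPlan:
    archetypes: tuple[ArchetypeSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [a.label for a in self.archetypes]
        if len(labels) != len(set(labels)):
            raise ValueError("archetype labels must be unique")
        if not labels:
            raise ValueError("cohort plan is empty")


def standard_cohort_plan(
    counts: dict[str, int], seed: int = 0, jitter: float = 0.05
) -> CohortPlan:
    """Cohort plan over the built-in archetypes, e.g.
    ``{"T1": 10, "T2": 10, "T3-control": 10}``."""
    specs = []
    for label, count in counts.items():
        if label not in ARCHETYPES:
            raise KeyError(f"unknown archetype {label!r}; "
                           f"choose from {sorted(ARCHETYPES)}")
        genotype = "patient" if "patient" in label else "control"
        specs.append(ArchetypeSpec(label=label, params=ARCHETYPES[label],
                                   count=count, jitter=jitter,
                                   genotype=genotype))
    return CohortPlan(archetypes=tuple(specs), seed=seed)


def _jitter_params(params: NeuronParams, jitter: float,
                   rng: np.random.Generator) -> NeuronParams:
    if jitter == 0:
        return params
    def mult(x: float) -> float:
        return float(x * np.exp(rng.normal(0.0, jitter)))
    rho = float(np.clip(params.rho * np.exp(rng.normal(0.0, jitter)), 0.0, 1.0))
    return replace(params, c_m=mult(params.c_m), g_na=mult(params.g_na),
                   g_k=mult(params.g_k), g_l=mult(params.g_l), rho=rho)


def generate_cohort(
    plan: CohortPlan,
    protocol: ProtocolDescriptor | None = None,
    dt_ms: float = 0.01,
) -> tuple[list[SweepRecording], pd.DataFrame]:
    """Simulate one recording per planned cell under ``protocol``.

    Returns the recordings plus a truth table (cell_id, label, genotype,
    rho). Per-cell jittered parameters are embedded in each recording's
    metadata. Deterministic given ``plan.seed``.
    """
    protocol = protocol or default_cc_protocol()
    rng = np.random.default_rng(plan.seed)
    recs: list[SweepRecording] = []
    rows = []
    idx = 0
    for spec in plan.archetypes:
        for _ in range(spec.count):
            cell_params = _jitter_params(spec.params, spec.jitter, rng)
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cell_id = f"cell_{idx:03d}"
            if protocol.mode is ClampMode.CURRENT_CLAMP:
                rec = simulate_current_clamp(
                    cell_params, protocol, dt_ms=dt_ms, seed=cell_seed,
                    cell_id=cell_id, genotype=spec.genotype)
            else:
                rec = simulate_voltage_clamp(
                    cell_params, protocol, dt_ms=dt_ms,
                    cell_id=cell_id, genotype=spec.genotype)
            rec.metadata["truth"]["label"] = spec.label
            recs.append(rec)
            rows.append({"cell_id": cell_id, "label": spec.label,
                         "genotype": spec.genotype, "rho": cell_params.rho})
            idx += 1
    return recs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# isotope tracing


#: carbon counts for the metabolites covered by the single-turn model
METABOLITE_CARBONS: dict[str, int] = {
    "glutamine": 5,
    "glutamate": 5,
    "2-oxoglutarate": 5,
    "citrate": 6,
    "malate": 4,
    "aspartate": 4,
}


@dataclass(frozen=True)
class TracingPlan:
    """Plan for a single-turn [U-13C]glutamine labelling panel.

    ``f_red`` is the reductive (carboxylation) fraction of labelled flux;
    ``dilution`` the unlabelled-pool fraction. Noise is either Gaussian on
    fractions (``noise_sigma``) or Dirichlet resampling
    (``dirichlet_conc``); both renormalise to sum 1.
    """

    f_red: float = 0.5
    dilution: float = 0.0
    n_replicates: int = 3
    noise_sigma: float = 0.0
    dirichlet_conc: float | None = None
    group: str = "control"
    metabolites: tuple[str, ...] = tuple(METABOLITE_CARBONS)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_red <= 1.0:
            raise ValueError("f_red must be in [0, 1]")
        if not 0.0 <= self.dilution <= 1.0:
            raise ValueError("dilution must be in [0, 1]")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be > 0")


def single_turn_mid(metabolite: str, f_red: float, dilution: float) -> np.ndarray:
    """Noise-free single-turn mass-isotopologue distribution.

    Uniformly labelled glutamine enters as glutamate and 2-oxoglutarate
    (M+5). Oxidative TCA flux yields citrate M+4 and malate/aspartate M+4;
    reductive carboxylation yields citrate M+5 and malate/aspartate M+3.
    The labelled mass splits f_red : (1 - f_red); a ``dilution`` fraction
    of each pool stays unlabelled (M0).
    """
    n = METABOLITE_CARBONS.get(metabolite)
    if n is None:
        raise KeyError(f"no single-turn pattern for {metabolite!r}")
    labelled = 1.0 - dilution
    mid = np.zeros(n + 1)
    mid[0] = dilution
    if metabolite in ("glutamine", "glutamate", "2-oxoglutarate"):
        mid[5] = labelled
    elif metabolite == "citrate":
        mid[5] += labelled * f_red
        mid[4] += labelled * (1.0 - f_red)
    else:  # malate, aspartate
        mid[3] += labelled * f_red
        mid[4] += labelled * (1.0 - f_red)
    return mid


def generate_mid_panel(plan: TracingPlan) -> tuple[pd.DataFrame, dict]:
    """Generate a tidy MID table plus the planted truth.

    Returns ``(table, truth)``; the table has one row per
    (sample, metabolite, isotopologue) with columns ``sample, group,
    metabolite, n_carbons, isotopologue, fraction``; fractions per
    (sample, metabolite) sum to 1.
    """
    rng = np.random.default_rng(plan.seed)
    rows = []
    for r in range(plan.n_replicates):
        sample = f"{plan.group}_rep{r + 1}"
        for met in plan.metabolites:
            n = METABOLITE_CARBONS[met]
            mid = single_turn_mid(met, plan.f_red, plan.dilution)
            if plan.dirichlet_conc is not None:
                mid = rng.dirichlet(plan.dirichlet_conc * mid + 1e-6)
            elif plan.noise_sigma > 0:
                mid = np.clip(mid + rng.normal(0, plan.noise_sigma, mid.size), 0, None)
                mid = mid / mid.sum()
            for i, frac in enumerate(mid):
                rows.append({"sample": sample, "group": plan.group,
                             "metabolite": met, "n_carbons": n,
                             "isotopologue": i, "fraction": float(frac)})
    truth = {"f_red": plan.f_red, "dilution": plan.dilution,
             "seed": plan.seed, "group": plan.group}
    return pd.DataFrame(rows), truth
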