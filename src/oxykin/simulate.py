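"""Forward simulation of Clark-electrode oxygen-consumption traces.

The simulator produces traces with exactly the structure the analysis
pipeline assumes: a pre-injection plateau decaying by electrode background
alone, an injection event, the lag (activation) phase, a maximal-rate phase,
cooperative shutoff as oxygen runs out, and additive Gaussian measurement
noise on top of a constant calibration offset.  An optional short
exponential disturbance after injection emulates mixing artifacts, giving
the pipeline's 20 s post-injection exclusion something real to exclude.

Besides the electrode's oxygen-proportional background, a small constant
chemical background sink (``chemical_background_rate``) emulates slow oxygen
consumption by the assay mix itself (GSH autoxidation, the coupled
glutathione-reductase/NADPH system).  It is what lets traces of highly
cooperative enzymes — whose enzymatic consumption shuts off at a few uM of
oxygen — deplete fully, as real chamber recordings do; without it the
"lowest oxygen concentration" normalization would have no true zero to find.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .models import KineticParameters, ModelSpec, observed_rate
from .presets import PRESETS
from .trace import AssayMetadata, OxygenTrace, write_trace

__all__ = ["SimulationConfig", "simulate_trace", "simulate_titration",
           "make_fixture_suite", "saturating_exponential"]


@dataclass
class SimulationConfig:
    """Ground truth and acquisition settings for one simulated run.

    Times in s, concentrations in uM.  ``params.ti`` is ignored; the
    injection happens at ``pre_injection_duration``.  ``calibration_offset``
    is a constant added to the recorded channel (the normalisation step of
    the pipeline must remove it).  ``chemical_background_rate`` (uM/s) is a
    constant oxygen sink from the assay mix, active throughout the run and
    tapering off smoothly only as oxygen nears zero; set it to 0 to simulate
    the fitted rate law and electrode background alone.
    ``mixing_artifact_amplitude`` > 0 adds a transient exponential bump
    (time constant ``mixing_artifact_tau``) right after injection.
    """

    params: KineticParameters
    spec: ModelSpec
    O2_initial: float = 250.0
    pre_injection_duration: float = 240.0
    total_duration: float = 1200.0
    sample_interval: float = 0.1
    noise_sd: float = 0.5
    calibration_offset: float = 2.0
    enzyme_conc: float = 1.0
    substrate_label: str = ""
    substrate_conc: float | None = None
    chemical_background_rate: float = 0.002
    mixing_artifact_amplitude: float = 0.0
    mixing_artifact_tau: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.O2_initial <= 0:
            raise ValueError("O2_initial must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.total_duration <= self.pre_injection_duration:
            raise ValueError("total_duration must exceed pre_injection_duration")

    def replace(self, **changes) -> "SimulationConfig":
        from dataclasses import replace
        return replace(self, **changes)


#: soft-floor constant (uM) making the chemical background sink vanish
#: smoothly as oxygen runs out
_CHEM_SOFT_K = 0.05


def _noise_free_oxygen(config: SimulationConfig,
                       times: np.ndarray) -> np.ndarray:
    """Integrate the model ODE over the sampling grid (no noise/offset)."""
    ti = config.pre_injection_duration
    p = config.params.replace(ti=ti)
    c0 = config.chemical_background_rate

    def chem(o2: float) -> float:
        return c0 * o2 / (o2 + _CHEM_SOFT_K) if c0 > 0 else 0.0

    pre = times < ti
    oxy = np.empty_like(times)

    if c0 > 0:
        def rhs_pre(t, y):
            o2 = max(y[0], 0.0)
            return [-(p.x * o2 + chem(o2))]

        sol_pre = solve_ivp(rhs_pre, (times[0], ti), [config.O2_initial],
                            t_eval=times[pre], method="LSODA",
                            rtol=1e-8, atol=1e-10)
        if not sol_pre.success:  # pragma: no cover
            raise RuntimeError(f"trace integration failed: {sol_pre.message}")
        oxy[pre] = sol_pre.y[0]
        O2_at_ti = float(sol_pre.y[0][-1]) if pre.any() else config.O2_initial
        # carry the background decay up to exactly t = ti
        if pre.any():
            dt_gap = ti - times[pre][-1]
            O2_at_ti = O2_at_ti - dt_gap * (p.x * O2_at_ti + chem(O2_at_ti))
    else:
        # background only: closed-form exponential decay
        oxy[pre] = config.O2_initial * np.exp(-p.x * times[pre])
        O2_at_ti = config.O2_initial * np.exp(-p.x * ti)

    post_t = times[~pre]
    if len(post_t):
        def rhs(t, y):
            o2 = max(y[0], 0.0)
            return [-(observed_rate(t, o2, p, config.spec) + chem(o2))]

        sol = solve_ivp(rhs, (ti, times[-1]), [O2_at_ti], t_eval=post_t,
                        method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"trace integration failed: {sol.message}")
        oxy[~pre] = np.minimum.accumulate(np.maximum(sol.y[0], 0.0))
    return oxy


def simulate_trace(config: SimulationConfig) -> OxygenTrace:
    """Generate one oxygen trace; deterministic in (config, seed)."""
    dt = config.sample_interval
    n = int(round(config.total_duration / dt)) + 1
    times = np.arange(n) * dt
    ti = config.pre_injection_duration

    oxy = _noise_free_oxygen(config, times)
    if config.mixing_artifact_amplitude > 0:
        post = times >= ti
        oxy = oxy + np.where(
            post,
            config.mixing_artifact_amplitude
            * np.exp(-(times - ti) / config.mixing_artifact_tau),
            0.0)
    oxy = oxy + config.calibration_offset
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        oxy = oxy + rng.normal(0.0, config.noise_sd, size=n)
    oxy = np.maximum(oxy, 0.0)

    meta = AssayMetadata(enzyme_conc=config.enzyme_conc,
                         substrate_label=config.substrate_label,
                         substrate_conc=config.substrate_conc,
                         injection_time=ti, sample_interval=dt)
    return OxygenTrace(times=times, oxygen=oxy, metadata=meta,
                       processing_log=[f"simulate_trace(seed={config.seed})"])


def saturating_exponential(c, baseline: float, amplitude: float,
                           midpoint: float, decreasing: bool = False):
    """Single pseudo-first-order law in concentration: the response moves
    from ``baseline`` (at c=0) toward ``baseline + amplitude`` (increasing)
    or decays from ``baseline + amplitude`` toward ``baseline`` (decreasing),
    reaching half the change at ``midpoint``."""
    c = np.asarray(c, dtype=float)
    e = np.exp(-c * np.log(2.0) / midpoint)
    out = baseline + amplitude * (e if decreasing else (1.0 - e))
    return out if out.ndim else float(out)


@dataclass
class TitrationSimulation:
    """Traces for a substrate titration plus the generating laws."""

    traces: list
    substrate_concs: np.ndarray
    truth: dict = field(default_factory=dict)


def simulate_titration(base_config: SimulationConfig, substrate_concs,
                       kcat_law: dict | None = None,
                       activation_law: dict | None = None) -> TitrationSimulation:
    """One trace per substrate concentration, with Vmax and activation rate
    constants transformed by saturating pseudo-first-order laws.

    ``kcat_law``: {"baseline", "amplitude", "midpoint"} for k_cat(c) (s^-1);
    ``activation_law``: {"k1": {...}, "k2": {...}} with the same keys per
    rate constant (min^-1), each optionally with "decreasing": True.
    Alternatively ``activation_law={"halftime": {...}}`` (one-step models
    only) drives the activation halftime (min) directly by the law and sets
    k1 = ln2 / halftime(c), emulating halftime-versus-substrate titrations.
    """
    substrate_concs = np.asarray(substrate_concs, dtype=float)
    if substrate_concs.size == 0:
        raise ValueError("substrate concentration list is empty")
    traces = []
    for i, c in enumerate(substrate_concs):
        p = base_config.params
        changes: dict = {}
        if kcat_law is not None:
            kcat = saturating_exponential(c, kcat_law["baseline"],
                                          kcat_law["amplitude"],
                                          kcat_law["midpoint"],
                                          kcat_law.get("decreasing", False))
            changes["vmax"] = kcat * base_config.enzyme_conc
        if activation_law is not None:
            if "halftime" in activation_law:
                if base_config.spec.activation != "one_step":
                    raise ValueError(
                        "halftime law requires a one-step activation model")
                law = activation_law["halftime"]
                ht = saturating_exponential(
                    c, law["baseline"], law["amplitude"], law["midpoint"],
                    law.get("decreasing", True))
                changes["k1"] = float(np.log(2.0) / ht)
            for key in ("k1", "k2", "k3"):
                if key in activation_law and getattr(p, key) is not None:
                    law = activation_law[key]
                    changes[key] = saturating_exponential(
                        c, law["baseline"], law["amplitude"], law["midpoint"],
                        law.get("decreasing", False))
        cfg = base_config.replace(params=p.replace(**changes),
                                  substrate_conc=float(c),
                                  seed=base_config.seed + i)
        traces.append(simulate_trace(cfg))
    return TitrationSimulation(traces=traces, substrate_concs=substrate_concs,
                               truth={"kcat_law": kcat_law,
                                      "activation_law": activation_law})


def _spec_dict(spec: ModelSpec) -> dict:
    return {"activation": spec.activation, "inactivation": spec.inactivation,
            "hill_fixed_to_one": spec.hill_fixed_to_one}


def make_fixture_suite(output_dir, seed: int = 0,
                       noise_levels: tuple[float, ...] = (0.0, 0.5),
                       sample_interval: float = 0.1) -> dict:
    """Write a canonical set of synthetic traces with known ground truth.

    One trace per (enzyme preset, noise level): Ero1a-like (two-step
    activation, n=5.2), Ero1b-like (one-step, n=3.1), Erv1p-like (no lag,
    n=1, low oxygen affinity), and a synthetic activation+inactivation
    enzyme.  Returns (and writes) a manifest with file names, seeds and true
    parameters; regenerating with the same seed reproduces identical files.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for pi, preset in enumerate(PRESETS.values()):
        for ni, noise in enumerate(noise_levels):
            cfg = SimulationConfig(
                params=preset.params, spec=preset.spec,
                enzyme_conc=preset.enzyme_conc,
                total_duration=preset.total_duration,
                sample_interval=sample_interval,
                noise_sd=noise, seed=seed + 100 * pi + ni)
            trace = simulate_trace(cfg)
            tag = preset.name.replace("-", "_").lower()
            fname = f"{tag}_noise{noise:g}.csv"
            write_trace(trace, outdir / fname)
            digest = hashlib.sha256((outdir / fname).read_bytes()).hexdigest()
            entries.append({
                "file": fname, "enzyme": preset.name, "noise_sd": noise,
                "seed": cfg.seed, "sha256": digest,
                "truth": {k: v for k, v in asdict(cfg.params).items()
                          if v is not None},
                "spec": _spec_dict(preset.spec),
            })
    manifest = {"seed": seed, "traces": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
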