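"""Synthetic coculture study generator with planted ground truth.

The generator emulates the full pairwise-interaction design: 5 species x 3
strains, every monoculture in biological triplicate and every unordered
strain pair in quadruplicate, OD600 sampled every 30 min for 24 h, and
10 000-event cytometry at T0/T24.  Species-level growth phenotypes are
seeded from observed wine-yeast monoculture kinetics; strains deviate from
their species mean by a multiplicative coefficient of variation.

Coculture dynamics follow a two-population generalized Lotka-Volterra
(competitive logistic) system with an optional toxicity term:

    dN_A/dt = r_A N_A (1 - (N_A + a_AB N_B) / K_A) - tau N_A N_B
    dN_B/dt = r_B N_B (1 - (N_B + a_BA N_A) / K_B) - tau N_A N_B

with each population held at its inoculum until its lag elapses.  The
plate reader sees only the total OD N_A + N_B.

The no-interaction null is **full niche overlap** (a = 1 with a common K),
not a = 0: with a total-OD readout, two independently growing populations
(a = 0) would stack two carrying capacities and masquerade as
overyielding.  Facilitation is planted as a < 1 (partial niche release),
antagonism as a > 1 and/or tau > 0; tau is what generates genuine
underyielding below both monocultures.

One master seed derives all randomness through numpy ``SeedSequence``
spawn keys: ``(0,)`` for the strain registry, ``(1, well_index)`` for
per-well lag jitter and OD noise, ``(2, well_index)`` for cytometry
draws — so any single well is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .clustering import InteractionMatrix
from .errors import AnalysisError
from .io_plate import (CultureDescriptor, CytometrySample, GrowthCurve, PlateLayout,
                       write_cytometry, write_layout, write_timeseries)

__all__ = [
    "SpeciesDefaults",
    "StrainParams",
    "InteractionSpec",
    "SimulationScenario",
    "SimulatedDataset",
    "SPECIES_DEFAULTS",
    "sample_strain_params",
    "simulate_pair",
    "emit_dataset",
    "neutral_scenario",
    "species_block_scenario",
    "planted_block_matrix",
]


@dataclass(frozen=True)
class SpeciesDefaults:
    """Species-level growth phenotype: capacity (OD), rate (1/h), lag (h)."""

    K: float
    r: float
    lag: float = 1.0


#: Species means seeded from observed wine-yeast monoculture kinetics.
SPECIES_DEFAULTS: dict[str, SpeciesDefaults] = {
    "Sc": SpeciesDefaults(K=2.11, r=0.43),
    "Lt": SpeciesDefaults(K=2.15, r=0.43),
    "Td": SpeciesDefaults(K=2.11, r=0.33),
    "Hu": SpeciesDefaults(K=1.62, r=0.30),
    "Sb": SpeciesDefaults(K=1.42, r=0.17),
}


@dataclass(frozen=True)
class StrainParams:
    """One strain's growth parameters (N0 is the per-member inoculum)."""

    strain: str
    species: str
    K: float
    r: float
    N0: float
    lag: float

    def __post_init__(self):
        if not (self.K > self.N0 > 0):
            raise AnalysisError(f"strain {self.strain}: need K > N0 > 0 (K={self.K}, N0={self.N0})")
        if self.r <= 0 or self.lag < 0:
            raise AnalysisError(f"strain {self.strain}: need r > 0 and lag >= 0")


@dataclass(frozen=True)
class InteractionSpec:
    """Planted species-level interaction structure.

    ``alpha`` maps ordered species pairs (affected, partner) to the niche
    overlap coefficient (1 = neutral full overlap); ``tau`` maps unordered
    species pairs to a symmetric toxicity rate (per OD per h).  Strain
    pairs may additionally jitter the species value multiplicatively.
    """

    alpha: dict = field(default_factory=dict)
    tau: dict = field(default_factory=dict)
    alpha_jitter_cv: float = 0.0
    tau_jitter_cv: float = 0.0
    label: str = "neutral"

    def get_alpha(self, affected: str, partner: str) -> float:
        a = float(self.alpha.get((affected, partner), 1.0))
        if a < 0:
            raise AnalysisError(f"alpha({affected},{partner}) must be >= 0")
        return a

    def get_tau(self, sp1: str, sp2: str) -> float:
        t = float(self.tau.get((sp1, sp2), self.tau.get((sp2, sp1), 0.0)))
        if t < 0:
            raise AnalysisError(f"tau({sp1},{sp2}) must be >= 0")
        return t


@dataclass(frozen=True)
class SimulationScenario:
    """Full in-silico study design (defaults = the emulated experiment)."""

    species: dict = field(default_factory=lambda: dict(SPECIES_DEFAULTS))
    interaction: InteractionSpec = field(default_factory=InteractionSpec)
    n_strains_per_species: int = 3
    n_mono: int = 3
    n_co: int = 4
    t_end: float = 24.0
    dt_sample: float = 0.5
    dt: float = 0.01
    sigma_od: float = 0.02
    lag_jitter_sd: float = 0.5
    strain_cv: float = 0.03
    n_events: int = 10_000
    n0_total: float = 0.01
    cytometry_monocultures: bool = False
    seed: int = 1

    def __post_init__(self):
        if self.n_mono < 2 or self.n_co < 2:
            raise AnalysisError("replicate counts must be >= 2")
        if self.sigma_od < 0 or self.lag_jitter_sd < 0 or self.strain_cv < 0:
            raise AnalysisError("noise magnitudes must be >= 0")

    def sample_times(self) -> np.ndarray:
        n = int(round(self.t_end / self.dt_sample))
        return np.linspace(0.0, self.t_end, n + 1)


@dataclass
class SimulatedDataset:
    """In-memory view of one emitted dataset plus its truth manifest."""

    curves: list
    layout: PlateLayout
    cytometry: list
    manifest: dict


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def sample_strain_params(species_defaults: dict, strain_cv: float, seed: int,
                         n_strains: int = 3, n0_total: float = 0.01) -> list[StrainParams]:
    """Draw the strain registry: ``n_strains`` per species, deterministic.

    Strain K, r and lag each deviate from the species mean by an
    independent multiplicative factor ~ Normal(1, strain_cv), floored at
    0.2 to keep parameters admissible.
    """
    if strain_cv < 0:
        raise AnalysisError("strain_cv must be >= 0")
    rng = _rng(seed, 0)
    registry = []
    for sp in sorted(species_defaults):
        d = species_defaults[sp]
        for k in range(1, n_strains + 1):
            fK, fr, fl = np.maximum(rng.normal(1.0, strain_cv, size=3), 0.2)
            registry.append(StrainParams(
                strain=f"{sp}-{k}", species=sp,
                K=d.K * fK, r=d.r * fr, N0=n0_total / 2.0, lag=d.lag * fl,
            ))
    return registry


def _integrate_batch(pa_arr, pb_arr, alpha_ab, alpha_ba, tau, lag_a, lag_b,
                     times, dt: float = 0.01):
    """Fixed-step RK4 integration of many independent wells at once.

    ``pa_arr``/``pb_arr`` are dicts of parameter arrays (r, K, N0) of
    length m; lags are per-member per-well.  Returns per-population
    trajectories at ``times`` with shape (len(times), m).
    """
    times = np.asarray(times, dtype=float)
    m = len(tau)
    r = np.stack([pa_arr["r"], pb_arr["r"]])
    K = np.stack([pa_arr["K"], pb_arr["K"]])
    alpha = np.stack([alpha_ab, alpha_ba])
    # lags snap to the integration grid so the growth switch-on falls on a
    # step boundary and every RK4 step sees a smooth right-hand side
    lag = np.round(np.stack([lag_a, lag_b]) / dt) * dt
    N = np.stack([pa_arr["N0"], pb_arr["N0"]]).astype(float)

    stride = max(int(round((times[1] - times[0]) / dt)), 1) if len(times) > 1 else 1
    if len(times) > 1 and abs(stride * dt - (times[1] - times[0])) > 1e-9:
        raise AnalysisError("integration step dt must divide the sampling interval")
    n_steps = int(round((times[-1] - times[0]) / dt))

    def rhs(N, active):
        other = N[::-1]
        growth = r * N * (1.0 - (N + alpha * other) / K) - tau * N * other
        return np.where(active, growth, 0.0)

    out = np.empty((len(times), 2, m))
    out[0] = N
    rec = 1
    for step in range(1, n_steps + 1):
        t0 = times[0] + (step - 1) * dt
        active = t0 > lag - dt / 2  # per-step gate, constant across stages
        k1 = rhs(N, active)
        k2 = rhs(N + dt / 2 * k1, active)
        k3 = rhs(N + dt / 2 * k2, active)
        k4 = rhs(N + dt * k3, active)
        N = np.clip(N + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, None)
        if step % stride == 0 and rec < len(times):
            out[rec] = N
            rec += 1
    return out[:, 0, :], out[:, 1, :]


def simulate_pair(params_a: StrainParams, params_b: StrainParams,
                  alpha_ab: float, alpha_ba: float, tau: float,
                  times, dt: float = 0.01, lag_a: float | None = None,
                  lag_b: float | None = None):
    """Deterministic two-population trajectory for one well.

    Returns ``(N_A, N_B)`` at ``times``; the total OD is their sum.  Lags
    default to each strain's own lag and may be overridden (replicate
    jitter is applied by the dataset emitter, not here).
    """
    if alpha_ab < 0 or alpha_ba < 0 or tau < 0:
        raise AnalysisError("alpha and tau must be >= 0")
    pa = {"r": np.array([params_a.r]), "K": np.array([params_a.K]), "N0": np.array([params_a.N0])}
    pb = {"r": np.array([params_b.r]), "K": np.array([params_b.K]), "N0": np.array([params_b.N0])}
    NA, NB = _integrate_batch(
        pa, pb, np.array([alpha_ab]), np.array([alpha_ba]), np.array([tau]),
        np.array([params_a.lag if lag_a is None else lag_a]),
        np.array([params_b.lag if lag_b is None else lag_b]),
        times, dt,
    )
    return NA[:, 0], NB[:, 0]


def _pair_coeffs(spec: InteractionSpec, sa: StrainParams, sb: StrainParams, seed: int):
    """Species-level coefficients with optional per-strain-pair jitter."""
    a_ab = spec.get_alpha(sa.species, sb.species)
    a_ba = spec.get_alpha(sb.species, sa.species)
    t = spec.get_tau(sa.species, sb.species)
    if spec.alpha_jitter_cv > 0 or spec.tau_jitter_cv > 0:
        # one deterministic draw per unordered strain pair; jitter only
        # modulates planted (non-neutral) coefficients
        key = "|".join(sorted((sa.strain, sb.strain)))
        h = zlib.crc32(key.encode()) % (2**31)
        rng = _rng(seed, 3, h)
        fa, fb = np.maximum(rng.normal(1.0, spec.alpha_jitter_cv, size=2), 0.05)
        ft = max(rng.normal(1.0, spec.tau_jitter_cv), 0.05)
        if a_ab != 1.0:
            a_ab *= fa
        if a_ba != 1.0:
            a_ba *= fb
        if t > 0:
            t *= ft
    return a_ab, a_ba, t


def _design(registry: list[StrainParams], scenario: SimulationScenario):
    """Ordered well list: (well_id, member_a, member_b, kind, replicate, run)."""
    wells = []
    for s in registry:
        for rep in range(1, scenario.n_mono + 1):
            run = "run1" if rep <= 2 else "run2"
            wells.append((f"mono-{s.strain}-r{rep}", s, s, "monoculture", rep, run))
    for i, sa in enumerate(registry):
        for sb in registry[i + 1:]:
            for rep in range(1, scenario.n_co + 1):
                run = "run1" if rep <= 2 else "run2"
                wells.append((f"co-{sa.strain}--{sb.strain}-r{rep}", sa, sb, "coculture", rep, run))
    return wells


def emit_dataset(scenario: SimulationScenario, outdir=None) -> SimulatedDataset:
    """Simulate the full design and (optionally) write the three CSVs.

    Writes ``timeseries.csv``, ``layout.csv``, ``cytometry.csv`` and
    ``truth_manifest.yaml`` when ``outdir`` is given; always returns the
    in-memory dataset with the truth manifest (every planted parameter and
    the intended/realized interaction per pair).
    """
    registry = sample_strain_params(scenario.species, scenario.strain_cv, scenario.seed,
                                    scenario.n_strains_per_species, scenario.n0_total)
    times = scenario.sample_times()
    wells = _design(registry, scenario)
    m = len(wells)

    # per-well lag jitter and OD noise drawn up front (one stream per well),
    # then one batched integration for all wells
    lag_a = np.empty(m)
    lag_b = np.empty(m)
    coeffs = np.empty((3, m))
    od_noise = np.zeros((len(times), m))
    for w, (wid, sa, sb, kind, rep, run) in enumerate(wells):
        rng = _rng(scenario.seed, 1, w)
        ja, jb = rng.normal(0.0, scenario.lag_jitter_sd, size=2)
        lag_a[w] = max(sa.lag + ja, 0.0)
        lag_b[w] = max(sb.lag + jb, 0.0)
        if scenario.sigma_od > 0:
            od_noise[:, w] = rng.normal(0.0, scenario.sigma_od, size=len(times))
        if kind == "monoculture":
            coeffs[:, w] = (1.0, 1.0, 0.0)  # two clones, full overlap, no toxicity
        else:
            coeffs[:, w] = _pair_coeffs(scenario.interaction, sa, sb, scenario.seed)
    pa = {k: np.array([getattr(s, k2) for _, s, _, _, _, _ in wells])
          for k, k2 in (("r", "r"), ("K", "K"), ("N0", "N0"))}
    pb = {k: np.array([getattr(s, k2) for _, _, s, _, _, _ in wells])
          for k, k2 in (("r", "r"), ("K", "K"), ("N0", "N0"))}
    NA, NB = _integrate_batch(pa, pb, coeffs[0], coeffs[1], coeffs[2],
                              lag_a, lag_b, times, scenario.dt)
    total = NA + NB

    curves, layout, cyto = [], PlateLayout(), []
    for w, (wid, sa, sb, kind, rep, run) in enumerate(wells):
        od = np.clip(total[:, w] + od_noise[:, w], 0.0, None)
        curves.append(GrowthCurve(wid, times, od))
        layout.wells[wid] = CultureDescriptor(
            culture_id=wid, kind=kind, strain_a=sa.strain, strain_b=sb.strain,
            species_a=sa.species, species_b=sb.species, replicate=rep, run=run,
        )
        if kind == "coculture" or scenario.cytometry_monocultures:
            gates = ((sa.strain, sb.strain) if kind == "coculture"
                     else (f"{sa.strain}|tag", f"{sa.strain}|wt"))
            crng = _rng(scenario.seed, 2, w)
            for tp, share_a in (("T0", NA[0, w] / total[0, w]), ("T24", NA[-1, w] / total[-1, w])):
                n_a, n_b = crng.multinomial(scenario.n_events, [share_a, 1.0 - share_a])
                cyto.append(CytometrySample(wid, tp, {gates[0]: int(n_a), gates[1]: int(n_b)}))

    manifest = _truth_manifest(scenario, registry, wells, coeffs)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_timeseries(curves, outdir / "timeseries.csv")
        write_layout(layout, outdir / "layout.csv")
        write_cytometry(cyto, outdir / "cytometry.csv")
        with open(outdir / "truth_manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return SimulatedDataset(curves=curves, layout=layout, cytometry=cyto, manifest=manifest)


def _truth_manifest(scenario, registry, wells, coeffs) -> dict:
    """Planted parameters plus the realized noise-free interaction index."""
    times = np.arange(0.0, scenario.t_end + 1e-9, 0.1)
    # noise-free units: every monoculture plus one well per unordered pair,
    # integrated in a single batch
    units: list[tuple[StrainParams, StrainParams, float, float, float]] = [
        (s, s, 1.0, 1.0, 0.0) for s in registry
    ]
    pair_keys: list[tuple[str, str]] = []
    seen = set()
    for w, (wid, sa, sb, kind, rep, run) in enumerate(wells):
        if kind != "coculture":
            continue
        key = tuple(sorted((sa.strain, sb.strain)))
        if key in seen:
            continue
        seen.add(key)
        pair_keys.append(key)
        a_ab, a_ba, tau = coeffs[:, w]
        units.append((sa, sb, float(a_ab), float(a_ba), float(tau)))
    pa = {k: np.array([getattr(u[0], k) for u in units]) for k in ("r", "K", "N0")}
    pb = {k: np.array([getattr(u[1], k) for u in units]) for k in ("r", "K", "N0")}
    NA, NB = _integrate_batch(
        pa, pb,
        np.array([u[2] for u in units]), np.array([u[3] for u in units]),
        np.array([u[4] for u in units]),
        np.array([u[0].lag for u in units]), np.array([u[1].lag for u in units]),
        times, scenario.dt,
    )
    aucs = np.trapezoid(NA + NB, times, axis=0)
    mono_auc = {s.strain: float(aucs[i]) for i, s in enumerate(registry)}
    pairs = {}
    for p, key in enumerate(pair_keys):
        sa, sb, a_ab, a_ba, tau = units[len(registry) + p]
        co_auc = float(aucs[len(registry) + p])
        ref = 0.5 * (mono_auc[sa.strain] + mono_auc[sb.strain])
        planted = (co_auc - ref) / ref
        antagonism = tau > 0 or a_ab > 1.0 or a_ba > 1.0
        facilitation = a_ab < 1.0 or a_ba < 1.0
        if not antagonism and not facilitation:
            intended = "0"
        elif antagonism and not facilitation:
            intended = "-"
        elif facilitation and not antagonism:
            intended = "+"
        else:
            intended = "+" if planted > 0 else "-"
        pairs["--".join(key)] = {
            "alpha_ab": float(a_ab), "alpha_ba": float(a_ba), "tau": float(tau),
            "planted_index_auc": float(planted), "intended_sign": intended,
        }
    return {
        "scenario": scenario.interaction.label,
        "seed": int(scenario.seed),
        "design": {
            "n_strains": len(registry),
            "n_mono_wells": len(registry) * scenario.n_mono,
            "n_co_wells": len(registry) * (len(registry) - 1) // 2 * scenario.n_co,
            "n_timepoints": len(scenario.sample_times()),
            "n_events": int(scenario.n_events),
        },
        "noise": {
            "sigma_od": float(scenario.sigma_od),
            "lag_jitter_sd": float(scenario.lag_jitter_sd),
            "strain_cv": float(scenario.strain_cv),
        },
        "strains": {
            s.strain: {"species": s.species, "K": float(s.K), "r": float(s.r),
                       "N0": float(s.N0), "lag": float(s.lag)}
            for s in registry
        },
        "monoculture_auc_noisefree": {k: float(v) for k, v in mono_auc.items()},
        "pairs": pairs,
    }


def neutral_scenario(seed: int = 1, **overrides) -> SimulationScenario:
    """Shared-niche no-interaction null: one common phenotype, alpha = 1.

    All species share one growth phenotype because with a total-OD readout
    a shared-niche coculture of unequal growers drifts toward the faster
    member and deviates from the monoculture midpoint even without any
    interaction; a calibration null needs exchangeable phenotypes.
    """
    common = SpeciesDefaults(K=2.0, r=0.40, lag=1.0)
    species = {sp: common for sp in SPECIES_DEFAULTS}
    defaults = dict(species=species, interaction=InteractionSpec(label="neutral"), seed=seed)
    defaults.update(overrides)
    return SimulationScenario(**defaults)


def species_block_scenario(seed: int = 1, **overrides) -> SimulationScenario:
    """Species-structured planted interactions on realistic phenotypes.

    Antagonism between the strong fermenters (Sc with Lt and Td: raised
    niche overlap plus toxicity) and facilitation in every Sb pairing
    (partial niche release), mirroring the pattern the interaction matrix
    is expected to resolve into species blocks.
    """
    alpha = {}
    tau = {}
    # raised overlap alone mostly swaps who wins without lowering the total
    # OD much, so genuine underyielding needs the toxicity term as well;
    # the Sc-Td contest settles quickly, so the pressure on Sc is raised
    # asymmetrically to keep the pair's total-OD deficit visible
    alpha[("Sc", "Lt")] = alpha[("Lt", "Sc")] = 1.5
    tau[("Sc", "Lt")] = 0.25
    alpha[("Sc", "Td")] = 2.5
    alpha[("Td", "Sc")] = 1.2
    tau[("Sc", "Td")] = 0.25
    for sp in ("Sc", "Lt", "Td", "Hu"):
        alpha[(sp, "Sb")] = alpha[("Sb", sp)] = 0.6
    spec = InteractionSpec(alpha=alpha, tau=tau, alpha_jitter_cv=0.05,
                           tau_jitter_cv=0.05, label="species-block")
    defaults = dict(species=dict(SPECIES_DEFAULTS), interaction=spec, seed=seed)
    defaults.update(overrides)
    return SimulationScenario(**defaults)


def planted_block_matrix(seed: int = 0, n_species: int = 5, strains_per_species: int = 3,
                         separation: float = 5.0, within_sd: float = 1.0,
                         parameter: str = "synthetic") -> tuple[InteractionMatrix, np.ndarray]:
    """Species-block interaction matrix with known labels.

    Every between-species pair mean sits ``separation * within_sd`` away
    from the (zero) within-species mean, and each pair value adds
    Normal(0, within_sd) noise, so every block pair is separated by the
    same margin and scaling ``separation`` scales all between-block mean
    differences uniformly.  Returns the matrix and the planted species
    labels per strain.
    """
    rng = np.random.default_rng(seed)
    mu = separation * within_sd * (1.0 - np.eye(n_species))
    labels = np.repeat(np.arange(n_species), strains_per_species)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = mu[labels[i], labels[j]] + rng.normal(0.0, within_sd)
    strains = tuple(f"S{a + 1}-{k + 1}" for a in range(n_species) for k in range(strains_per_species))
    species = tuple(f"S{a + 1}" for a in labels)
    mat = InteractionMatrix(parameter, strains, species, values, np.zeros((n, n), dtype=bool))
    return mat, labels
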