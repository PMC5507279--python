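"""Published experiment presets, outcome classification, and the
stabilization criterion.

Five experiments are provided.  Experiments 1-4 mutate only the parasites
(replicases fixed at a_R = 0.7, l_R = 0, i.e. always catalytically active
and always available as templates):

1. a_P0 = 0.55, l_P0 = 0.2, both parasite attributes mutable at 0.01;
2. l_P0 swept 0..1 in steps of 0.1, a_P fixed at 0.55, mu_l = 0.19;
3. a_P0 swept 0..1, l_P fixed at 0.2, mu_a = 0.19;
4. a_P0 swept 0..1 but immutable, l_P mutable at mu_l = 0.19.

Experiment 5 mutates all four attributes at 0.01 and varies the initial
(a_P0, a_R0) pair over a seven-pair grid, under both circle and random
placement, with l_P0 = l_R0 = 0.2.

All presets carry the published kinetic constant set (see
``KineticParams``).  Besides the full-scale arena, a scaled-down variant
of every preset is provided for desk-size runs; see ``_SCALED_STEPS`` and
the methods note for the chosen sizes.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticParams, MutationParams

#: initial (a_P0, a_R0) pairs of the fifth experiment
EXPERIMENT5_PAIRS = [
    (0.3, 0.5),
    (0.4, 0.6),
    (0.4, 0.7),
    (0.55, 0.6),
    (0.55, 0.7),
    (0.8, 0.6),
    (0.8, 0.7),
]

_SWEEP = [round(0.1 * i, 1) for i in range(11)]

# step limits per experiment at full scale / desk scale
_FULL_STEPS = {1: 150000, 2: 150000, 3: 16000, 4: 150000, 5: 150000}
_SCALED_STEPS = {1: 20000, 2: 20000, 3: 16000, 4: 20000, 5: 20000}


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce one run."""

    width: float = 256.0
    height: float = 256.0
    n_replicases: int = 2500
    n_parasites: int = 2500
    placement: str = "circle"          # "circle" or "random"
    disc_radius: float = 64.0
    a_R0: float = 0.7
    l_R0: float = 0.0
    a_P0: float = 0.55
    l_P0: float = 0.2
    kinetics: KineticParams = field(default_factory=KineticParams)
    mutation: MutationParams = field(default_factory=MutationParams)
    max_steps: int = 150000
    seed: int = 0
    decay_mode: str = "frozen"         # or "ticking"
    offspring_offset: float = 0.0

    def validate(self) -> None:
        for name in ("a_R0", "l_R0", "a_P0", "l_P0"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_replicases < 0 or self.n_parasites < 0:
            raise ValueError("initial counts must be non-negative")
        if self.placement not in ("circle", "random"):
            raise ValueError("placement must be 'circle' or 'random'")
        if self.placement == "circle":
            if not (0 < self.disc_radius <= min(self.width, self.height) / 2):
                raise ValueError("disc radius must fit inside the arena")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if self.decay_mode not in ("ticking", "frozen"):
            raise ValueError("decay_mode must be 'ticking' or 'frozen'")
        if self.offspring_offset < 0:
            raise ValueError("offspring_offset must be non-negative")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        # re-run the parameter invariants
        KineticParams(**vars(self.kinetics))
        MutationParams(**vars(self.mutation))


def _base(scaled: bool) -> ScenarioConfig:
    """Common world for the presets.  Both scales use the calibrated
    crowding cap n_max = 6 (see methods note); the desk scale is the
    smallest arena at which the wave ecosystem is viable."""
    if scaled:
        cfg = ScenarioConfig(width=256.0, height=256.0,
                             n_replicases=2500, n_parasites=2500,
                             disc_radius=45.0)
    else:
        cfg = ScenarioConfig(width=512.0, height=512.0,
                             n_replicases=10000, n_parasites=10000,
                             disc_radius=90.0)
    cfg.kinetics = KineticParams(n_max=6)
    return cfg


def preset(experiment_id: int, variant_index: int | None = None,
           scaled: bool = False) -> list[ScenarioConfig]:
    """Configurations of one published experiment.

    Returns the full variant list (a single config for experiment 1, the
    eleven-point sweeps for 2-4, the 7x2 placement grid for 5), or a
    one-element list when ``variant_index`` is given.
    """
    if experiment_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown experiment id {experiment_id!r}")
    steps = (_SCALED_STEPS if scaled else _FULL_STEPS)[experiment_id]
    configs: list[ScenarioConfig] = []

    if experiment_id == 1:
        cfg = _base(scaled)
        cfg.a_P0, cfg.l_P0 = 0.55, 0.2
        cfg.mutation = MutationParams(mu_a=0.01, mu_l=0.01,
                                      mutate_a_parasite=True,
                                      mutate_l_parasite=True)
        cfg.max_steps = steps
        configs = [cfg]
    elif experiment_id == 2:
        for l0 in _SWEEP:
            cfg = _base(scaled)
            cfg.a_P0, cfg.l_P0 = 0.55, l0
            cfg.mutation = MutationParams(mu_l=0.19, mutate_l_parasite=True)
            cfg.max_steps = steps
            configs.append(cfg)
    elif experiment_id == 3:
        for a0 in _SWEEP:
            cfg = _base(scaled)
            cfg.a_P0, cfg.l_P0 = a0, 0.2
            cfg.mutation = MutationParams(mu_a=0.19, mutate_a_parasite=True)
            cfg.max_steps = steps
            configs.append(cfg)
    elif experiment_id == 4:
        for a0 in _SWEEP:
            cfg = _base(scaled)
            cfg.a_P0, cfg.l_P0 = a0, 0.2
            cfg.mutation = MutationParams(mu_l=0.19, mutate_l_parasite=True)
            cfg.max_steps = steps
            configs.append(cfg)
    else:
        for a_p, a_r in EXPERIMENT5_PAIRS:
            for placement in ("circle", "random"):
                cfg = _base(scaled)
                cfg.a_P0, cfg.a_R0 = a_p, a_r
                cfg.l_P0 = cfg.l_R0 = 0.2
                cfg.placement = placement
                cfg.mutation = MutationParams(
                    mu_a=0.01, mu_l=0.01,
                    mutate_a_replicase=True, mutate_l_replicase=True,
                    mutate_a_parasite=True, mutate_l_parasite=True)
                cfg.max_steps = steps
                configs.append(cfg)

    if variant_index is not None:
        if not (0 <= variant_index < len(configs)):
            raise ValueError(
                f"experiment {experiment_id} has {len(configs)} variants; "
                f"index {variant_index} is out of range")
        return [configs[variant_index]]
    return configs


def classify_outcome(result, max_steps: int) -> str:
    """Label a finished run: "survived" iff both species counts (complexed
    members included) are positive at the step limit; otherwise by which
    species reached zero (both, if at the same step)."""
    last = result.timeseries.iloc[-1]
    n_r, n_p = int(last["n_R_total"]), int(last["n_P_total"])
    if n_r > 0 and n_p > 0:
        if result.final_step < max_steps:
            raise ValueError("run did not reach the step limit nor extinction")
        return "survived"
    if n_r == 0 and n_p == 0:
        return "extinct_both"
    return "extinct_parasites" if n_p == 0 else "extinct_replicases"


def detect_stabilization(series, window: int, tol: float) -> int | None:
    """Earliest index from which the least-squares slope of every trailing
    window (of the given length, in consecutive recorded points) stays
    strictly below ``tol`` in magnitude through the end of the series.

    Returns the index (into ``series``) of the end of the first such
    window, or None if the slopes never settle (including series shorter
    than one window).
    """
    if window < 2:
        raise ValueError("window must span at least two points")
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < window:
        return None
    x = np.arange(window, dtype=float)
    x -= x.mean()
    denom = float(np.sum(x * x))
    # slope of the window *ending* at index k+window-1
    num = np.convolve(y, x[::-1], mode="valid")
    slopes = num / denom
    ok = np.abs(slopes) < tol
    if not ok[-1]:
        return None
    bad = np.where(~ok)[0]
    first_ok = int(bad[-1] + 1) if bad.size else 0
    return first_ok + window - 1


# ---------------------------------------------------------------------------
# Config file round trip (TOML)
# ---------------------------------------------------------------------------

def config_to_toml(cfg: ScenarioConfig) -> str:
    """Serialize a configuration to its TOML dialect (see read side for
    the section layout; unknown keys are rejected on read)."""
    kin = cfg.kinetics
    mut = cfg.mutation

    def b(v):  # TOML booleans
        return "true" if v else "false"

    return (
        "[world]\n"
        f"width = {cfg.width!r}\n"
        f"height = {cfg.height!r}\n"
        "\n[kinetics]\n"
        f"d = {kin.d!r}\n"
        f"D = {kin.D!r}\n"
        f"D_complex = {kin.D_complex!r}\n"
        f"K = {kin.K!r}\n"
        f"dt = {kin.dt!r}\n"
        f"radius = {kin.radius!r}\n"
        f"n_max = {kin.n_max}\n"
        "\n[mutation]\n"
        f"mu_a = {mut.mu_a!r}\n"
        f"mu_l = {mut.mu_l!r}\n"
        f"delta = {mut.delta!r}\n"
        "\n[species.replicase]\n"
        f"n0 = {cfg.n_replicases}\n"
        f"a0 = {cfg.a_R0!r}\n"
        f"l0 = {cfg.l_R0!r}\n"
        f"mutate_a = {b(mut.mutate_a_replicase)}\n"
        f"mutate_l = {b(mut.mutate_l_replicase)}\n"
        "\n[species.parasite]\n"
        f"n0 = {cfg.n_parasites}\n"
        f"a0 = {cfg.a_P0!r}\n"
        f"l0 = {cfg.l_P0!r}\n"
        f"mutate_a = {b(mut.mutate_a_parasite)}\n"
        f"mutate_l = {b(mut.mutate_l_parasite)}\n"
        "\n[init]\n"
        f'placement = "{cfg.placement}"\n'
        f"disc_radius = {cfg.disc_radius!r}\n"
        "\n[run]\n"
        f"max_steps = {cfg.max_steps}\n"
        f"seed = {cfg.seed}\n"
        f'decay_mode = "{cfg.decay_mode}"\n'
        f"offspring_offset = {cfg.offspring_offset!r}\n"
    )


class ConfigError(ValueError):
    """Malformed or unknown content in a configuration file."""


def _take(section: dict, section_name: str, keys: dict):
    """Pop known keys with defaults; any leftover key is an error."""
    out = {}
    for key, default in keys.items():
        out[key] = section.pop(key, default)
    if section:
        raise ConfigError(
            f"unknown keys in [{section_name}]: {sorted(section)}")
    return out


def config_from_toml(text: str) -> ScenarioConfig:
    """Parse the TOML config dialect.  Unknown sections or keys raise
    ``ConfigError`` (fail-fast against typos)."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML: {exc}") from exc

    base = ScenarioConfig()
    kin_default = KineticParams()
    mut_default = MutationParams()

    world = _take(data.pop("world", {}), "world",
                  {"width": base.width, "height": base.height})
    kin = _take(data.pop("kinetics", {}), "kinetics",
                {"d": kin_default.d, "D": kin_default.D,
                 "D_complex": kin_default.D_complex, "K": kin_default.K,
                 "dt": kin_default.dt, "radius": kin_default.radius,
                 "n_max": kin_default.n_max})
    mut = _take(data.pop("mutation", {}), "mutation",
                {"mu_a": mut_default.mu_a, "mu_l": mut_default.mu_l,
                 "delta": mut_default.delta})
    species = data.pop("species", {})
    rep = _take(species.pop("replicase", {}), "species.replicase",
                {"n0": base.n_replicases, "a0": base.a_R0, "l0": base.l_R0,
                 "mutate_a": False, "mutate_l": False})
    par = _take(species.pop("parasite", {}), "species.parasite",
                {"n0": base.n_parasites, "a0": base.a_P0, "l0": base.l_P0,
                 "mutate_a": False, "mutate_l": False})
    if species:
        raise ConfigError(f"unknown species sections: {sorted(species)}")
    init = _take(data.pop("init", {}), "init",
                 {"placement": base.placement,
                  "disc_radius": base.disc_radius})
    runsec = _take(data.pop("run", {}), "run",
                   {"max_steps": base.max_steps, "seed": base.seed,
                    "decay_mode": base.decay_mode,
                    "offspring_offset": base.offspring_offset})
    if data:
        raise ConfigError(f"unknown sections: {sorted(data)}")

    cfg = ScenarioConfig(
        width=float(world["width"]), height=float(world["height"]),
        n_replicases=int(rep["n0"]), n_parasites=int(par["n0"]),
        placement=str(init["placement"]),
        disc_radius=float(init["disc_radius"]),
        a_R0=float(rep["a0"]), l_R0=float(rep["l0"]),
        a_P0=float(par["a0"]), l_P0=float(par["l0"]),
        kinetics=KineticParams(
            d=float(kin["d"]), D=float(kin["D"]),
            D_complex=float(kin["D_complex"]), K=float(kin["K"]),
            dt=float(kin["dt"]), radius=float(kin["radius"]),
            n_max=int(kin["n_max"])),
        mutation=MutationParams(
            mu_a=float(mut["mu_a"]), mu_l=float(mut["mu_l"]),
            delta=float(mut["delta"]),
            mutate_a_replicase=bool(rep["mutate_a"]),
            mutate_l_replicase=bool(rep["mutate_l"]),
            mutate_a_parasite=bool(par["mutate_a"]),
            mutate_l_parasite=bool(par["mutate_l"])),
        max_steps=int(runsec["max_steps"]), seed=int(runsec["seed"]),
        decay_mode=str(runsec["decay_mode"]),
        offspring_offset=float(runsec["offspring_offset"]))
    cfg.validate()
    return cfg
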