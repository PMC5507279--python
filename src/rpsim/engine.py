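"""The step scheduler and run loop.

The world advances in discrete steps of length dt.  All state lives in the
parallel entity arrays consumed by the compiled kernel in
``rpsim._kernel``; this module owns initialization, capacity management,
the per-step molecule-conservation audit, extinction detection, and the
object-level views (``Molecule`` / ``Complex`` dataclasses) used for
inspection and for exercising individual reaction rules in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel as K
from . import _rng
from .kinetics import (
    KineticParams,
    MutationParams,
    reaction_probability,
    sample_waiting_time,
)
from .world import (
    PARASITE,
    REPLICASE,
    Complex,
    Molecule,
    TorusGeometry,
    torus_midpoint,
)

_SP_CODE = {REPLICASE: K.SP_R, PARASITE: K.SP_P}
_SP_NAME = {K.SP_R: REPLICASE, K.SP_P: PARASITE}

#: column order of the per-step time series
TIMESERIES_COLUMNS = [
    "step", "time",
    "n_R_free", "n_P_free", "n_RR_complexes", "n_RP_complexes",
    "n_R_total", "n_P_total",
    "mean_a_R", "std_a_R", "mean_l_R", "std_l_R",
    "mean_a_P", "std_a_P", "mean_l_P", "std_l_P",
]


@dataclass
class EventLog:
    """Per-step event counters; reconciled against the molecule ledger."""

    decays_free: int = 0
    decays_in_complex: int = 0
    dissociations: int = 0
    replications: int = 0
    complex_formations: int = 0
    overcrowd_removals: int = 0        # entities removed by crowding
    overcrowd_molecules: int = 0       # molecules those entities contained


class LedgerError(RuntimeError):
    """The molecule-conservation audit failed — internal inconsistency."""


class WorldState:
    """All simulation state: entity arrays, geometry, clocks, RNG stream."""

    def __init__(self, geom: TorusGeometry, kin: KineticParams, rng_state,
                 capacity: int = 1024, decay_mode: str = "ticking"):
        if decay_mode not in ("ticking", "frozen"):
            raise ValueError("decay_mode must be 'ticking' or 'frozen'")
        rc = 2.0 * kin.radius
        gw = int(geom.width // rc)
        gh = int(geom.height // rc)
        if gw < 3 or gh < 3:
            raise ValueError(
                "arena must span at least three collision distances per axis")
        self.geom = geom
        self.kin = kin
        self.decay_mode = decay_mode
        self.rng = rng_state
        self.time = 0.0
        self.step_count = 0
        self.next_id = 0
        self.n_top = 0
        self._gw, self._gh = gw, gh
        self._grid_valid = False
        self._alloc(max(capacity, 64))
        self._out = np.zeros(K.OUT_LEN)
        self._nbr = np.zeros(K.NBR_CAP, dtype=np.int32)

    # -- storage ---------------------------------------------------------
    def _alloc(self, cap: int) -> None:
        self.ent = np.zeros((cap, K.NF))
        self.alive = np.zeros(cap, dtype=np.uint8)
        self.kind = np.zeros(cap, dtype=np.uint8)
        self.sp = np.zeros(cap, dtype=np.uint8)
        self.mid = np.zeros(cap, dtype=np.int64)
        self.cid = np.full(cap, -1, dtype=np.int64)
        self._head = np.full(self._gw * self._gh, -1, dtype=np.int32)
        self._nxt = np.full(cap, -1, dtype=np.int32)
        self._prv = np.full(cap, -1, dtype=np.int32)
        self._cellof = np.full(cap, -1, dtype=np.int32)
        self._order = np.zeros(cap, dtype=np.int32)

    @property
    def capacity(self) -> int:
        return self.ent.shape[0]

    def _grow(self, cap: int) -> None:
        old = (self.ent, self.alive, self.kind, self.sp, self.mid, self.cid)
        n = self.n_top
        self._alloc(cap)
        self.ent[:n] = old[0][:n]
        self.alive[:n] = old[1][:n]
        self.kind[:n] = old[2][:n]
        self.sp[:n] = old[3][:n]
        self.mid[:n] = old[4][:n]
        self.cid[:n] = old[5][:n]
        self._grid_valid = False

    def _ensure_capacity(self) -> None:
        n_alive = int(self.alive[:self.n_top].sum())
        need = 4 * n_alive + 64
        if self.capacity < need:
            self._grow(max(need, 2 * self.capacity))

    # -- bookkeeping -----------------------------------------------------
    def _record(self) -> np.ndarray:
        K.record_kernel(self.ent, self.alive, self.kind, self.sp,
                        self.n_top, self._out)
        return self._out

    def counts(self) -> tuple[int, int, int, int]:
        """(n_R_free, n_P_free, n_RR, n_RP) over living entities."""
        out = self._record()
        return (int(out[K.O_NRF]), int(out[K.O_NPF]),
                int(out[K.O_NRR]), int(out[K.O_NRP]))

    def totals(self) -> tuple[int, int]:
        """(replicases, parasites) counting complexed members: an RR
        complex holds two replicases, an RP complex one of each."""
        nrf, npf, nrr, nrp = self.counts()
        return nrf + 2 * nrr + nrp, npf + nrp

    def n_molecules(self) -> int:
        nr, np_ = self.totals()
        return nr + np_

    # -- entity construction (used by initialization and tests) ----------
    def add_molecule(self, species: str, x: float, y: float, a: float,
                     l: float, rlt: float) -> int:
        """Append one free molecule; returns its id."""
        if self.n_top + 1 > self.capacity:
            self._grow(2 * self.capacity + 64)
        i = self.n_top
        self.ent[i, :] = 0.0
        self.ent[i, K.F_X] = x
        self.ent[i, K.F_Y] = y
        self.ent[i, K.F_A] = a
        self.ent[i, K.F_L] = l
        self.ent[i, K.F_RLT] = rlt
        self.alive[i] = 1
        self.kind[i] = K.KIND_FREE
        self.sp[i] = _SP_CODE[species]
        ident = self.next_id
        self.mid[i] = ident
        self.cid[i] = -1
        self.next_id += 1
        self.n_top += 1
        self._grid_valid = False
        return ident

    def add_complex(self, template_species: str, x: float, y: float,
                    tpl_a: float, tpl_l: float, tpl_rlt: float,
                    cat_a: float, cat_l: float, cat_rlt: float,
                    ttr: float, dissociation_rlt: float) -> tuple[int, int]:
        """Append one bound pair directly (initialization/testing hook);
        returns (catalyst id, template id)."""
        if self.n_top + 1 > self.capacity:
            self._grow(2 * self.capacity + 64)
        i = self.n_top
        self.ent[i, :] = 0.0
        self.ent[i, K.F_X] = x
        self.ent[i, K.F_Y] = y
        self.ent[i, K.F_A] = tpl_a
        self.ent[i, K.F_L] = tpl_l
        self.ent[i, K.F_RLT] = tpl_rlt
        self.ent[i, K.F_TTR] = ttr
        self.ent[i, K.F_DISS] = dissociation_rlt
        self.ent[i, K.F_CA] = cat_a
        self.ent[i, K.F_CL] = cat_l
        self.ent[i, K.F_CRLT] = cat_rlt
        self.alive[i] = 1
        self.kind[i] = K.KIND_CPLX
        self.sp[i] = _SP_CODE[template_species]
        cat_id = self.next_id
        tpl_id = self.next_id + 1
        self.cid[i] = cat_id
        self.mid[i] = tpl_id
        self.next_id += 2
        self.n_top += 1
        self._grid_valid = False
        return cat_id, tpl_id

    # -- object-level views ----------------------------------------------
    def free_molecules(self) -> list[Molecule]:
        out = []
        for i in range(self.n_top):
            if self.alive[i] and self.kind[i] == K.KIND_FREE:
                out.append(Molecule(
                    id=int(self.mid[i]), species=_SP_NAME[int(self.sp[i])],
                    x=float(self.ent[i, K.F_X]), y=float(self.ent[i, K.F_Y]),
                    a=float(self.ent[i, K.F_A]), l=float(self.ent[i, K.F_L]),
                    rlt=max(0.0, float(self.ent[i, K.F_RLT])),
                    radius=self.kin.radius))
        return out

    def complexes(self) -> list[Complex]:
        out = []
        for i in range(self.n_top):
            if self.alive[i] and self.kind[i] == K.KIND_CPLX:
                x = float(self.ent[i, K.F_X])
                y = float(self.ent[i, K.F_Y])
                cat = Molecule(
                    id=int(self.cid[i]), species=REPLICASE, x=x, y=y,
                    a=float(self.ent[i, K.F_CA]), l=float(self.ent[i, K.F_CL]),
                    rlt=max(0.0, float(self.ent[i, K.F_CRLT])),
                    radius=self.kin.radius)
                tpl = Molecule(
                    id=int(self.mid[i]), species=_SP_NAME[int(self.sp[i])],
                    x=x, y=y,
                    a=float(self.ent[i, K.F_A]), l=float(self.ent[i, K.F_L]),
                    rlt=max(0.0, float(self.ent[i, K.F_RLT])),
                    radius=self.kin.radius)
                out.append(Complex(
                    catalyst=cat, template=tpl, x=x, y=y,
                    ttr=max(0.0, float(self.ent[i, K.F_TTR])),
                    dissociation_rlt=max(0.0, float(self.ent[i, K.F_DISS])),
                    stored_catalyst_rlt=float(self.ent[i, K.F_CRLT]),
                    stored_template_rlt=float(self.ent[i, K.F_RLT])))
        return out


@dataclass
class RunResult:
    """Outcome of one run: label, final step, full time series, final state."""

    outcome: str
    final_step: int
    timeseries: pd.DataFrame
    final_state: WorldState
    events: EventLog


def initialize_world(config, rng=None) -> WorldState:
    """Build the initial world from a scenario configuration.

    Placement is either "circle" (the two species fill opposite half-discs
    of a disc centered in the arena — replicases the upper half, parasites
    the lower) or "random" (uniform over the whole torus).  All replicases
    share (a_R0, l_R0) and all parasites (a_P0, l_P0); every lifetime is
    an exponential draw at the decay rate.  Draw order: replicases first,
    then parasites; per molecule, position draws then the lifetime draw.
    """
    config.validate()
    if rng is None:
        rng = _rng.make_state(config.seed)
    geom = TorusGeometry(config.width, config.height)
    kin = config.kinetics
    rc = 2.0 * kin.radius

    # refuse initial densities beyond the crowding rule's carrying density
    n_total = config.n_replicases + config.n_parasites
    if config.placement == "circle":
        region_area = math.pi * config.disc_radius ** 2
    else:
        region_area = config.width * config.height
    if region_area > 0 and n_total / region_area > kin.n_max / (math.pi * kin.radius ** 2):
        raise ValueError("initial molecule density exceeds the crowding capacity")

    state = WorldState(geom, kin, rng, capacity=4 * n_total + 64,
                       decay_mode=config.decay_mode)
    cx, cy = config.width / 2.0, config.height / 2.0

    def place(species, n, a0, l0, upper):
        for _ in range(n):
            if config.placement == "circle":
                r = config.disc_radius * math.sqrt(_rng.uniform(rng))
                th = math.pi * _rng.uniform(rng)
                if not upper:
                    th += math.pi
                x = (cx + r * math.cos(th)) % config.width
                y = (cy + r * math.sin(th)) % config.height
            else:
                x = config.width * _rng.uniform(rng)
                y = config.height * _rng.uniform(rng)
            rlt = (K.INF if kin.d <= 0.0
                   else sample_waiting_time(kin.d, _rng.open_uniform(rng)))
            state.add_molecule(species, x, y, a0, l0, rlt)

    place(REPLICASE, config.n_replicases, config.a_R0, config.l_R0, True)
    place(PARASITE, config.n_parasites, config.a_P0, config.l_P0, False)
    return state


def _effective_mus(config) -> tuple[float, float, float, float]:
    mut = config.mutation
    return (mut.effective_mu(REPLICASE, "a"), mut.effective_mu(REPLICASE, "l"),
            mut.effective_mu(PARASITE, "a"), mut.effective_mu(PARASITE, "l"))


def step(state: WorldState, kin: KineticParams, mut: MutationParams,
         mus: tuple[float, float, float, float] | None = None,
         offspring_offset: float = 1.0) -> tuple[WorldState, EventLog]:
    """Advance the world by one step; returns the state and event counts.

    Raises ``LedgerError`` if the molecule count does not balance:
    Delta(total) must equal replications - decays - crowding removals
    (complex formation and dissociation conserve molecules).
    """
    before = state.n_molecules()
    state._ensure_capacity()
    # compact on a fixed state-derived schedule (dead rows exceed half the
    # live ones), so trajectories depend only on (config, seed)
    n_alive = int(state.alive[:state.n_top].sum())
    do_compact = (not state._grid_valid
                  or state.n_top > n_alive + n_alive // 2 + 64)
    if mus is None:
        mus = (mut.effective_mu(REPLICASE, "a"), mut.effective_mu(REPLICASE, "l"),
               mut.effective_mu(PARASITE, "a"), mut.effective_mu(PARASITE, "l"))
    n_top, next_id = K.step_kernel(
        state.ent, state.alive, state.kind, state.sp, state.mid, state.cid,
        state._head, state._nxt, state._prv, state._cellof,
        state._gw, state._gh,
        state.geom.width, state.geom.height,
        kin.dt, kin.d, kin.D, kin.D_complex, kin.K, 2.0 * kin.radius,
        kin.n_max,
        mus[0], mus[1], mus[2], mus[3], mut.delta, offspring_offset,
        state.decay_mode == "ticking",
        state.n_top, state.next_id, do_compact,
        state._order, state._nbr, state.rng, state._out)
    if state._out[K.O_ERR] != 0.0:
        raise RuntimeError("entity capacity exhausted mid-step")
    state.n_top = n_top
    state.next_id = next_id
    state._grid_valid = True
    state.time += kin.dt
    state.step_count += 1
    out = state._out
    log = EventLog(
        decays_free=int(out[K.O_DECF]),
        decays_in_complex=int(out[K.O_DECC]),
        dissociations=int(out[K.O_DISS]),
        replications=int(out[K.O_REPL]),
        complex_formations=int(out[K.O_FORM]),
        overcrowd_removals=int(out[K.O_OVE]),
        overcrowd_molecules=int(out[K.O_OVM]),
    )
    after = (int(out[K.O_NRF]) + int(out[K.O_NPF])
             + 2 * (int(out[K.O_NRR]) + int(out[K.O_NRP])))
    expected = (before + log.replications - log.decays_free
                - log.decays_in_complex - log.overcrowd_molecules)
    if after != expected:
        raise LedgerError(
            f"molecule ledger imbalance at step {state.step_count}: "
            f"{before} -> {after}, expected {expected}")
    return state, log


def _row_from_out(step_i: int, time: float, out: np.ndarray) -> np.ndarray:
    row = np.full(len(TIMESERIES_COLUMNS), np.nan)
    nrf, npf = out[K.O_NRF], out[K.O_NPF]
    nrr, nrp = out[K.O_NRR], out[K.O_NRP]
    n_r = nrf + 2 * nrr + nrp
    n_p = npf + nrp
    row[0] = step_i
    row[1] = time
    row[2:8] = (nrf, npf, nrr, nrp, n_r, n_p)
    if n_r > 0:
        ma = out[K.O_SAR] / n_r
        ml = out[K.O_SLR] / n_r
        row[8] = ma
        row[9] = math.sqrt(max(0.0, out[K.O_SAR2] / n_r - ma * ma))
        row[10] = ml
        row[11] = math.sqrt(max(0.0, out[K.O_SLR2] / n_r - ml * ml))
    if n_p > 0:
        ma = out[K.O_SAP] / n_p
        ml = out[K.O_SLP] / n_p
        row[12] = ma
        row[13] = math.sqrt(max(0.0, out[K.O_SAP2] / n_p - ma * ma))
        row[14] = ml
        row[15] = math.sqrt(max(0.0, out[K.O_SLP2] / n_p - ml * ml))
    return row


def run(config, rng=None, observers=()) -> RunResult:
    """Run a scenario to its step limit or to extinction of either species.

    ``observers`` are callables invoked as ``observer(state, log)`` after
    every step (and once at step 0 with ``log=None``); attaching them
    changes nothing about the trajectory.
    """
    if config.max_steps <= 0:
        raise ValueError("max_steps must be positive")
    state = initialize_world(config, rng=rng)
    kin = config.kinetics
    mut = config.mutation
    mus = _effective_mus(config)

    rows = np.empty((config.max_steps + 1, len(TIMESERIES_COLUMNS)))
    state._record()
    rows[0] = _row_from_out(0, 0.0, state._out)
    for obs in observers:
        obs(state, None)

    totals = EventLog()
    n_rows = 1
    outcome = None
    n_r, n_p = state.totals()
    if n_r == 0 or n_p == 0:
        outcome = _extinction_label(n_r, n_p)
    else:
        while state.step_count < config.max_steps:
            _, log = step(state, kin, mut, mus=mus,
                          offspring_offset=config.offspring_offset)
            rows[n_rows] = _row_from_out(state.step_count, state.time, state._out)
            n_rows += 1
            for name in EventLog.__dataclass_fields__:
                setattr(totals, name, getattr(totals, name) + getattr(log, name))
            for obs in observers:
                obs(state, log)
            n_r = int(rows[n_rows - 1][6])
            n_p = int(rows[n_rows - 1][7])
            if n_r == 0 or n_p == 0:
                outcome = _extinction_label(n_r, n_p)
                break
        if outcome is None:
            outcome = "survived"

    ts = pd.DataFrame(rows[:n_rows], columns=TIMESERIES_COLUMNS)
    ts["step"] = ts["step"].astype(int)
    for col in ("n_R_free", "n_P_free", "n_RR_complexes", "n_RP_complexes",
                "n_R_total", "n_P_total"):
        ts[col] = ts[col].astype(int)
    return RunResult(outcome=outcome, final_step=state.step_count,
                     timeseries=ts, final_state=state, events=totals)


def _extinction_label(n_r: int, n_p: int) -> str:
    if n_r == 0 and n_p == 0:
        return "extinct_both"
    if n_p == 0:
        return "extinct_parasites"
    return "extinct_replicases"


# ---------------------------------------------------------------------------
# Object-level reaction rules.  These small functions state the model's
# pairing and lifecycle rules on explicit Molecule/Complex values; the
# compiled kernel applies the identical rules in bulk.
# ---------------------------------------------------------------------------

def attempt_complex_formation(x: Molecule, candidate: Molecule,
                              kin: KineticParams, rng,
                              geom: TorusGeometry | None = None) -> Complex | None:
    """Try to bind an initiating molecule to one collision partner.

    Template selection: a parasite in the pair is always the template;
    between two replicases the non-initiating molecule (``candidate``) is.
    With probability ``omega = a_t * (1 - l_t)`` a complex forms at the
    pair's torus midpoint, with a replication clock at rate K and a
    dissociation clock at rate ``1 - a_t`` (infinite when ``a_t = 1``);
    otherwise the collision was elastic and None is returned.
    """
    if x.species == PARASITE and candidate.species == PARASITE:
        raise ValueError("two parasites can never bind")
    if x.species == PARASITE:
        template, catalyst = x, candidate
    elif candidate.species == PARASITE:
        template, catalyst = candidate, x
    else:
        template, catalyst = candidate, x
    omega = reaction_probability(template.a, template.l)
    if _rng.uniform(rng) >= omega:
        return None
    if geom is not None:
        mx, my = torus_midpoint((x.x, x.y), (candidate.x, candidate.y), geom)
    else:
        mx, my = (0.5 * (x.x + candidate.x), 0.5 * (x.y + candidate.y))
    ttr = sample_waiting_time(kin.K, _rng.open_uniform(rng))
    a_d = 1.0 - template.a
    diss = (K.INF if a_d <= 0.0
            else sample_waiting_time(a_d, _rng.open_uniform(rng)))
    return Complex(catalyst=catalyst, template=template, x=mx, y=my,
                   ttr=ttr, dissociation_rlt=diss,
                   stored_catalyst_rlt=catalyst.rlt,
                   stored_template_rlt=template.rlt)


def replicate(c: Complex, kin: KineticParams, mut: MutationParams,
              rng, next_id: int = -1,
              offspring_offset: float = 1.0) -> tuple[Molecule, Molecule, Molecule]:
    """Fire an expired replication clock: copy the template (species, a, l),
    mutate the copy's attributes per the scenario's mutability flags, and
    release catalyst and template.  Returns (offspring, catalyst, template).
    """
    if c.ttr > 0:
        raise ValueError("replication clock has not expired")
    from .kinetics import mutate_attribute

    sp_name = c.template.species
    a = mutate_attribute(c.template.a, mut.effective_mu(sp_name, "a"),
                         mut.delta, rng)
    l = mutate_attribute(c.template.l, mut.effective_mu(sp_name, "l"),
                         mut.delta, rng)
    rlt = (K.INF if kin.d <= 0.0
           else sample_waiting_time(kin.d, _rng.open_uniform(rng)))
    th = 2.0 * math.pi * _rng.uniform(rng)
    offspring = Molecule(
        id=next_id, species=sp_name,
        x=c.x + offspring_offset * math.cos(th),
        y=c.y + offspring_offset * math.sin(th),
        a=a, l=l, rlt=min(rlt, K.INF), radius=c.template.radius)
    catalyst, template = dissociate(c)
    return offspring, catalyst, template


def dissociate(c: Complex) -> tuple[Molecule, Molecule]:
    """Release both components at the complex position with their stored
    lifetime clocks; molecule count is conserved (-1 complex, +2 free)."""
    cat = Molecule(id=c.catalyst.id, species=REPLICASE, x=c.x, y=c.y,
                   a=c.catalyst.a, l=c.catalyst.l,
                   rlt=max(0.0, c.stored_catalyst_rlt),
                   radius=c.catalyst.radius)
    tpl = Molecule(id=c.template.id, species=c.template.species, x=c.x, y=c.y,
                   a=c.template.a, l=c.template.l,
                   rlt=max(0.0, c.stored_template_rlt),
                   radius=c.template.radius)
    return cat, tpl
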