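"""Seeded generators emulating the statistical structure of the monitoring data.

Four generators produce the inputs each analysis stage expects, so the whole
pipeline is exercisable (and its estimators testable against known truth)
without any field data:

* a founder-bottleneck Wright-Fisher microsatellite population drifting away
  from a source population calibrated to expected heterozygosity 0.592, with
  an optional late injection of outbred immigrants whose alleles occupy a
  disjoint identifier range (so immigrant ancestry is detectable as private
  alleles);
* a half-normal spatial capture-recapture sampler over a regular trap grid
  with optional sex and trap-specific behavioral effects;
* GPS tracks alternating kill-handling phases (fixes jittered around a kill
  site for a gamma-distributed handling time) with correlated-random-walk
  travel, with gamma-distributed inter-kill intervals;
* right-censored survival times in three monitoring groups with a
  mortality-cause mix.

Every generator takes a :class:`numpy.random.Generator`; :class:`SimConfig`
derives one independent stream per stage from a single seed, so identical
configurations yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .popgen import MISSING, Destination, GenotypeTable, Group
from .predation import GpsTrack
from .scr import CaptureDataset, SessionData, StateSpaceGrid, build_state_space
from .survival import EndStatus

__all__ = [
    "DriftConfig",
    "ScrSimConfig",
    "TrackConfig",
    "SurvivalSimConfig",
    "SimConfig",
    "calibrate_source_frequencies",
    "simulate_drift_population",
    "simulate_scr_dataset",
    "simulate_tracks",
    "simulate_survival",
    "simulate_pedigree_trios",
    "match_clusters_to_kills",
    "write_all",
]


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class DriftConfig:
    """Founder bottleneck + drift + reinforcement history.

    Defaults mirror the monitored system: 6 founders, 19 microsatellite loci,
    source expected heterozygosity 0.592, four decades of drift at a small
    effective size, then translocated immigrants late in the series.
    """

    n_founders: int = 6
    n_loci: int = 19
    alleles_per_locus: int = 6
    source_he: float = 0.592
    he_tolerance: float = 0.01
    effective_size: int = 20
    post_reinforcement_size: int = 50
    generations: int = 40
    samples_per_generation: int = 6
    start_year: int = 1984
    immigrant_generation: int | None = 36
    immigrant_arrival_span: int = 4
    n_immigrants_dinaric: int = 8
    n_immigrants_alpine: int = 12
    alpine_samples_per_generation: int = 2
    immigrant_allele_offset: int = 100


@dataclass
class ScrSimConfig:
    """Half-normal SCR sampler; defaults give the parameter-recovery conditions."""

    density_per_100km2: float = 1.0
    p0: float = 0.1
    sigma: float = 2500.0
    trap_nx: int = 6
    trap_ny: int = 6
    trap_spacing: float = 2500.0
    buffer: float = 7500.0
    cell: float = 2500.0
    n_sessions: int = 3
    n_occasions: int = 10
    sex_logit_effect: float = 0.0       # added to logit p0 for males
    sigma_sex_log_effect: float = 0.0   # added to log sigma for males
    behavior_logit_effect: float = 0.0  # added after first capture at a trap


@dataclass
class TrackConfig:
    """Two-phase (kill-handling / travel) GPS track generator.

    Inter-kill intervals and handling (feeding) times are gamma with the field
    means; travel steps are far larger than the cluster radius so travel fixes
    do not cluster.
    """

    n_animals: int = 5
    duration_days: float = 60.0
    fixes_per_day: float = 3.0
    interkill_mean_days: float = 4.37
    interkill_shape: float = 2.0
    handling_mean_days: float = 2.41
    handling_shape: float = 2.0
    handling_jitter_m: float = 80.0     # < half the 200-m cluster radius
    travel_step_m: float = 2000.0
    turning_concentration: float = 4.0  # von Mises kappa for the travel walk
    no_kills: bool = False
    start_time: str = "2021-05-01T00:00:00"


@dataclass
class SurvivalSimConfig:
    """Exponential survival in the three monitoring groups, uniform censoring."""

    n_per_group: dict = field(
        default_factory=lambda: {"translocated": 22, "f1": 10, "remnant": 18}
    )
    hazard_per_day: dict = field(
        default_factory=lambda: {"translocated": 5e-4, "f1": 3e-4, "remnant": 1e-3}
    )
    max_follow_up_days: float = 1444.0
    disappeared_fraction: float = 0.1
    start_date: str = "2019-05-01"
    natural_fraction: dict = field(
        default_factory=lambda: {"translocated": 0.0, "f1": 0.0, "remnant": 0.65}
    )


@dataclass
class SimConfig:
    """One seed, one block per generator; the seed is split per stage."""

    seed: int = 0
    drift: DriftConfig = field(default_factory=DriftConfig)
    scr: ScrSimConfig = field(default_factory=ScrSimConfig)
    tracks: TrackConfig = field(default_factory=TrackConfig)
    survival: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)

    _STAGES = ("drift", "scr", "tracks", "survival")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible stream for one stage."""
        idx = self._STAGES.index(stage)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(idx,))
        )


# ---------------------------------------------------------------------------
# Drift population


def calibrate_source_frequencies(
    rng: np.random.Generator,
    n_loci: int,
    alleles_per_locus: int,
    target_he: float,
    tolerance: float = 0.01,
    allele_offset: int = 0,
    max_tries: int = 10_000,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-locus (allele ids, frequencies) with expected He near the target.

    Frequencies are Dirichlet(1,...,1) draws resampled until the locus
    gene diversity 1 - sum(p^2) is within ``tolerance`` of ``target_he``.
    Raises when the target is unattainable for the allele count (the maximum
    gene diversity with k alleles is 1 - 1/k).
    """
    max_he = 1.0 - 1.0 / alleles_per_locus
    if target_he > max_he + tolerance:
        raise ValueError(
            f"target He {target_he} unattainable with {alleles_per_locus} alleles "
            f"(max {max_he:.3f}); increase alleles_per_locus"
        )
    out = []
    for j in range(n_loci):
        ids = np.arange(1, alleles_per_locus + 1) + allele_offset
        for _ in range(max_tries):
            p = rng.dirichlet(np.ones(alleles_per_locus))
            if abs(1.0 - float(np.sum(p**2)) - target_he) <= tolerance:
                out.append((ids, p))
                break
        else:  # pragma: no cover - practically unreachable at default settings
            raise RuntimeError("calibration loop failed to hit the target He")
    return out


def _draw_genotypes(
    rng: np.random.Generator,
    freqs: list[tuple[np.ndarray, np.ndarray]],
    n: int,
) -> np.ndarray:
    geno = np.zeros((n, len(freqs), 2), dtype=np.int64)
    for j, (ids, p) in enumerate(freqs):
        geno[:, j, :] = rng.choice(ids, size=(n, 2), p=p)
    return geno


class _Pop:
    """Mutable diploid population state for the drift simulator."""

    def __init__(self, geno, ids, ancestry, transloc, dest, parents):
        self.geno = geno              # (n, L, 2)
        self.ids = list(ids)
        self.ancestry = np.asarray(ancestry, float)   # immigrant-ancestry fraction
        self.transloc = np.asarray(transloc, bool)    # is a translocated founder
        self.dest = list(dest)
        self.parents = dict(parents)                  # id -> (mother, father)

    def group_of(self, i: int, parent_transloc: bool) -> str:
        if self.transloc[i]:
            return Group.TRANSLOCATED.value
        if self.ancestry[i] == 0:
            return Group.REMNANT.value
        if parent_transloc:
            return Group.OFFSPRING_F1.value
        return Group.OFFSPRING_LATER.value

    def next_generation(self, size: int, rng, id_prefix: str, counter: int):
        n_loci = self.geno.shape[1]
        new_geno = np.zeros((size, n_loci, 2), dtype=np.int64)
        new_anc = np.zeros(size)
        new_ids, new_dest = [], []
        parent_tr = np.zeros(size, dtype=bool)
        for m in range(size):
            mi, fi = rng.choice(len(self.ids), size=2, replace=False)
            arange = np.arange(n_loci)
            new_geno[m, :, 0] = self.geno[mi, arange, rng.integers(0, 2, n_loci)]
            new_geno[m, :, 1] = self.geno[fi, arange, rng.integers(0, 2, n_loci)]
            new_anc[m] = (self.ancestry[mi] + self.ancestry[fi]) / 2.0
            parent_tr[m] = self.transloc[mi] or self.transloc[fi]
            iid = f"{id_prefix}{counter:04d}"
            counter += 1
            new_ids.append(iid)
            self.parents[iid] = (self.ids[mi], self.ids[fi])
            if new_anc[m] > 0:
                dm, df_ = self.dest[mi], self.dest[fi]
                new_dest.append(dm if dm != Destination.NONE.value else df_)
            else:
                new_dest.append(Destination.NONE.value)
        pop = _Pop(new_geno, new_ids, new_anc, np.zeros(size, bool),
                   new_dest, self.parents)
        pop._parent_tr = parent_tr
        return pop, counter


def simulate_drift_population(
    config: DriftConfig, rng: np.random.Generator
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Founder-bottleneck drift with staged immigrant reinforcement.

    The core (Dinaric) population drifts from the calibrated source allele
    frequencies at a small effective size.  From ``immigrant_generation``,
    translocated immigrants with a disjoint allele range arrive over
    ``immigrant_arrival_span`` generations: one cohort joins (and stays in)
    the core breeding pool, whose size steps up to
    ``post_reinforcement_size``; the other founds a separate stepping-stone
    (Alpine) subpopulation breeding among itself, sampled every later
    generation.  Returns the chronological genotype table and a truth sidecar
    with generation, true parents and immigrant-ancestry fraction for every
    sampled individual.
    """
    if config.n_founders < 2:
        raise ValueError("need at least two founders")
    source = calibrate_source_frequencies(
        rng, config.n_loci, config.alleles_per_locus,
        config.source_he, config.he_tolerance,
    )
    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]

    founders = _draw_genotypes(rng, source, config.n_founders)
    fid = [f"R{i:04d}" for i in range(config.n_founders)]
    core = _Pop(
        founders, fid, np.zeros(config.n_founders),
        np.zeros(config.n_founders, bool),
        [Destination.NONE.value] * config.n_founders,
        {i: (None, None) for i in fid},
    )
    core._parent_tr = np.zeros(config.n_founders, bool)
    alpine: _Pop | None = None
    counter = config.n_founders

    records: list[dict] = []
    truth_rows: list[dict] = []
    recorded: set[str] = set()

    def record(pop: _Pop, i: int, gen: int, month_day: str, grp: str | None = None):
        iid = pop.ids[i]
        if iid in recorded:
            return
        recorded.add(iid)
        parent_tr = getattr(pop, "_parent_tr", np.zeros(len(pop.ids), bool))
        grp = grp or pop.group_of(i, bool(parent_tr[i]))
        date = f"{config.start_year + gen}-{month_day}-{10 + (len(records) % 18):02d}"
        records.append(
            {
                "individual_id": iid,
                "sample_date": date,
                "group": grp,
                "destination": pop.dest[i],
                "_geno": pop.geno[i].copy(),
            }
        )
        truth_rows.append(
            {
                "individual_id": iid,
                "generation": gen,
                "group": grp,
                "destination": pop.dest[i],
                "mother": pop.parents[iid][0],
                "father": pop.parents[iid][1],
                "immigrant_ancestry": pop.ancestry[i],
            }
        )

    def sample(pop: _Pop, k: int, gen: int, month_day: str = "06") -> None:
        if k <= 0 or len(pop.ids) == 0:
            return
        pick = rng.choice(len(pop.ids), size=min(k, len(pop.ids)), replace=False)
        for i in sorted(pick):
            record(pop, i, gen, month_day)

    # arrival schedules: totals spread evenly over the arrival span
    def schedule(total: int) -> dict[int, int]:
        if config.immigrant_generation is None or total == 0:
            return {}
        span = max(config.immigrant_arrival_span, 1)
        base = np.full(span, total // span)
        base[: total % span] += 1
        return {
            config.immigrant_generation + i: int(base[i]) for i in range(span)
        }

    din_sched = schedule(config.n_immigrants_dinaric)
    alp_sched = schedule(config.n_immigrants_alpine)
    immigrant_freqs = None
    arrived_din: list[tuple[np.ndarray, str]] = []
    n_din_made = 0
    n_alp_made = 0

    def make_immigrants(n: int, prefix: str, start_idx: int):
        nonlocal immigrant_freqs
        if immigrant_freqs is None:
            immigrant_freqs = calibrate_source_frequencies(
                rng, config.n_loci, config.alleles_per_locus,
                config.source_he, config.he_tolerance,
                allele_offset=config.immigrant_allele_offset,
            )
        g = _draw_genotypes(rng, immigrant_freqs, n)
        ids = [f"{prefix}{start_idx + m:03d}" for m in range(n)]
        return g, ids

    sample(core, config.samples_per_generation, 0)
    for gen in range(1, config.generations + 1):
        # --- arrivals this generation
        if gen in din_sched:
            g, ids = make_immigrants(din_sched[gen], "T", n_din_made)
            n_din_made += len(ids)
            core.geno = np.concatenate([core.geno, g], axis=0)
            core.ids += ids
            core.ancestry = np.concatenate([core.ancestry, np.ones(len(ids))])
            core.transloc = np.concatenate([core.transloc, np.ones(len(ids), bool)])
            core.dest += [Destination.DINARIC.value] * len(ids)
            core._parent_tr = np.concatenate(
                [core._parent_tr, np.zeros(len(ids), bool)]
            )
            for m, iid in enumerate(ids):
                core.parents[iid] = (None, None)
                arrived_din.append((g[m], iid))
                record(core, len(core.ids) - len(ids) + m, gen, "04",
                       grp=Group.TRANSLOCATED.value)
        if gen in alp_sched:
            g, ids = make_immigrants(alp_sched[gen], "A", n_alp_made)
            n_alp_made += len(ids)
            if alpine is None:
                alpine = _Pop(
                    g, ids, np.ones(len(ids)), np.ones(len(ids), bool),
                    [Destination.ALPINE_STEPPING_STONE.value] * len(ids),
                    core.parents,
                )
                alpine._parent_tr = np.zeros(len(ids), bool)
            else:
                alpine.geno = np.concatenate([alpine.geno, g], axis=0)
                alpine.ids += ids
                alpine.ancestry = np.concatenate([alpine.ancestry, np.ones(len(ids))])
                alpine.transloc = np.concatenate(
                    [alpine.transloc, np.ones(len(ids), bool)]
                )
                alpine.dest += [Destination.ALPINE_STEPPING_STONE.value] * len(ids)
                alpine._parent_tr = np.concatenate(
                    [alpine._parent_tr, np.zeros(len(ids), bool)]
                )
            for iid in ids:
                alpine.parents[iid] = (None, None)
            for m in range(len(ids)):
                record(alpine, len(alpine.ids) - len(ids) + m, gen, "05",
                       grp=Group.TRANSLOCATED.value)

        # --- core breeding (translocated animals stay in the pool)
        reinforced = (
            config.immigrant_generation is not None
            and gen >= config.immigrant_generation
        )
        ne = config.post_reinforcement_size if reinforced else config.effective_size
        prev_parents = core.parents
        offspring, counter = core.next_generation(ne, rng, "R", counter)
        if reinforced and arrived_din:
            g = np.stack([x[0] for x in arrived_din])
            ids = [x[1] for x in arrived_din]
            offspring.geno = np.concatenate([offspring.geno, g], axis=0)
            offspring.ids += ids
            offspring.ancestry = np.concatenate(
                [offspring.ancestry, np.ones(len(ids))]
            )
            offspring.transloc = np.concatenate(
                [offspring.transloc, np.ones(len(ids), bool)]
            )
            offspring.dest += [Destination.DINARIC.value] * len(ids)
            offspring._parent_tr = np.concatenate(
                [offspring._parent_tr, np.zeros(len(ids), bool)]
            )
        core = offspring
        del prev_parents
        sample(core, config.samples_per_generation, gen)

        # --- stepping-stone breeding
        if alpine is not None:
            n_keep = max(len(alpine.ids), 6)
            alp_off, counter = alpine.next_generation(n_keep, rng, "AO", counter)
            alp_off.dest = [Destination.ALPINE_STEPPING_STONE.value] * len(alp_off.ids)
            alpine = alp_off
            sample(alpine, config.alpine_samples_per_generation, gen, month_day="07")

    meta = pd.DataFrame(
        [{k: v for k, v in r.items() if k != "_geno"} for r in records]
    )
    gmat = np.stack([r["_geno"] for r in records])
    table = GenotypeTable(meta, gmat, loci)
    truth = pd.DataFrame(truth_rows)
    return table, truth


def simulate_pedigree_trios(
    rng: np.random.Generator,
    n_trios: int = 100,
    n_loci: int = 19,
    alleles_per_locus: int = 6,
    n_unrelated: int = 20,
) -> tuple[GenotypeTable, GenotypeTable, pd.DataFrame]:
    """Error-free Mendelian trios plus unrelated candidates for parentage tests.

    Returns (offspring table, candidate table, truth frame with the true
    mother/father id per offspring).  Candidate sexes alternate so every trio
    has one female and one male true parent.
    """
    freqs = calibrate_source_frequencies(
        rng, n_loci, alleles_per_locus, target_he=0.70, tolerance=0.08
    )
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    n_cand = 2 * n_trios + n_unrelated
    cand_geno = _draw_genotypes(rng, freqs, n_cand)
    cand_ids = [f"C{i:04d}" for i in range(n_cand)]
    sexes = ["female" if i % 2 == 0 else "male" for i in range(n_cand)]

    off_geno = np.zeros((n_trios, n_loci, 2), dtype=np.int64)
    truth = []
    for t in range(n_trios):
        mi, fi = 2 * t, 2 * t + 1
        off_geno[t, :, 0] = cand_geno[mi, np.arange(n_loci), rng.integers(0, 2, n_loci)]
        off_geno[t, :, 1] = cand_geno[fi, np.arange(n_loci), rng.integers(0, 2, n_loci)]
        truth.append(
            {"offspring_id": f"O{t:04d}", "mother": cand_ids[mi], "father": cand_ids[fi]}
        )

    def _table(ids, geno, sex=None):
        meta = pd.DataFrame(
            {
                "individual_id": ids,
                "sample_date": "2022-01-01",
                "group": "unknown",
                "destination": "none",
            }
        )
        if sex is not None:
            meta["sex"] = sex
        return GenotypeTable(meta, geno, loci)

    offspring = _table([r["offspring_id"] for r in truth], off_geno)
    candidates = _table(cand_ids, cand_geno, sexes)
    return offspring, candidates, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# SCR sampler


def simulate_scr_dataset(
    config: ScrSimConfig, rng: np.random.Generator
) -> tuple[CaptureDataset, StateSpaceGrid, dict]:
    """Sample detections from the half-normal encounter model.

    Activity centers are uniform over the state-space cells, N per session is
    Poisson(D * A); only detected individuals enter the dataset.  The truth
    dict holds the generating parameters and per-session realized N.
    """
    gx, gy = np.meshgrid(
        np.arange(config.trap_nx) * config.trap_spacing,
        np.arange(config.trap_ny) * config.trap_spacing,
        indexing="ij",
    )
    trap_xy = np.column_stack([gx.ravel(), gy.ravel()])
    traps = pd.DataFrame(
        {
            "trap_id": [f"T{j:03d}" for j in range(len(trap_xy))],
            "x": trap_xy[:, 0],
            "y": trap_xy[:, 1],
            "location_type": "marking_site",
        }
    )
    grid = build_state_space(traps, buffer=config.buffer, cell=config.cell)
    lam = config.density_per_100km2 / 100.0 * grid.area_km2

    sessions = []
    n_true = []
    for s in range(config.n_sessions):
        n = int(rng.poisson(lam))
        n_true.append(n)
        cells = rng.integers(0, grid.n_cells, size=n)
        centers = grid.centers[cells] + rng.uniform(
            -config.cell / 2, config.cell / 2, size=(n, 2)
        )
        sex_male = rng.integers(0, 2, size=n)
        d2 = ((centers[:, None, :] - trap_xy[None, :, :]) ** 2).sum(axis=2)
        from scipy.special import expit, logit

        lp0 = logit(config.p0) + config.sex_logit_effect * sex_male[:, None]
        sig = config.sigma * np.exp(config.sigma_sex_log_effect * sex_male[:, None])
        p_naive = expit(lp0) * np.exp(-d2 / (2 * sig**2))  # (n, traps)

        if config.behavior_logit_effect == 0.0:
            u = rng.random((n, len(trap_xy), config.n_occasions))
            det = (u < p_naive[:, :, None]).astype(np.int8)
        else:
            det = np.zeros((n, len(trap_xy), config.n_occasions), dtype=np.int8)
            lp_b = lp0 + config.behavior_logit_effect
            p_b = expit(lp_b) * np.exp(-d2 / (2 * sig**2))
            caught = np.zeros((n, len(trap_xy)), dtype=bool)
            for k in range(config.n_occasions):
                p = np.where(caught, p_b, p_naive)
                hit = rng.random((n, len(trap_xy))) < p
                det[:, :, k] = hit
                caught |= hit

        seen = det.sum(axis=(1, 2)) > 0
        inds = pd.DataFrame(
            {
                "individual_id": [f"S{s}_I{i:03d}" for i in np.flatnonzero(seen)],
                "sex": np.where(sex_male[seen] == 1, "male", "female"),
            }
        )
        sessions.append(
            SessionData(
                session=f"Y{s + 1}",
                traps=traps.copy(),
                individuals=inds,
                n_occasions=config.n_occasions,
                detections=det[seen],
            )
        )
    truth = {
        "density_per_100km2": config.density_per_100km2,
        "p0": config.p0,
        "sigma": config.sigma,
        "n_true": n_true,
        "area_km2": grid.area_km2,
        "sex_logit_effect": config.sex_logit_effect,
    }
    return CaptureDataset(sessions), grid, truth


# ---------------------------------------------------------------------------
# GPS tracks


def simulate_tracks(
    config: TrackConfig, rng: np.random.Generator
) -> tuple[list[GpsTrack], pd.DataFrame]:
    """Two-phase kill/travel tracks with a known kill list.

    During handling, fixes sit at the kill site with uniform-disk jitter below
    half the clustering radius; between kills the animal performs a correlated
    random walk with steps much longer than the radius.  Returns the tracks
    and a truth frame ``animal_id, kill_time, x, y, handling_days``.
    """
    if config.fixes_per_day <= 0:
        raise ValueError("fix rate must be positive")
    t0 = pd.Timestamp(config.start_time)
    dt_days = 1.0 / config.fixes_per_day
    tracks = []
    kills = []
    for a in range(config.n_animals):
        aid = f"LYNX{a:02d}"
        # kill schedule
        events = []  # (start_day, handling_days, x, y)
        if not config.no_kills:
            t = float(rng.gamma(config.interkill_shape,
                                config.interkill_mean_days / config.interkill_shape))
            pos = np.array([0.0, 0.0])
            heading = rng.uniform(0, 2 * np.pi)
            while t < config.duration_days:
                handling = float(
                    rng.gamma(config.handling_shape,
                              config.handling_mean_days / config.handling_shape)
                )
                gap = float(rng.gamma(config.interkill_shape,
                                      config.interkill_mean_days / config.interkill_shape))
                handling = min(handling, max(gap - 0.25, 0.1))
                heading += rng.vonmises(0.0, config.turning_concentration)
                travel = config.travel_step_m * max(gap - handling, 0.5) * config.fixes_per_day / 4
                pos = pos + travel * np.array([np.cos(heading), np.sin(heading)]) / config.fixes_per_day
                events.append((t, handling, pos[0], pos[1]))
                t += gap
        # fix schedule
        times = np.arange(0.0, config.duration_days, dt_days)
        xy = np.zeros((len(times), 2))
        pos = np.array([0.0, 0.0])
        heading = rng.uniform(0, 2 * np.pi)
        ev = 0
        for i, ti in enumerate(times):
            while ev < len(events) and ti > events[ev][0] + events[ev][1]:
                ev += 1
            if ev < len(events) and events[ev][0] <= ti <= events[ev][0] + events[ev][1]:
                r = rng.uniform(0, config.handling_jitter_m)
                th = rng.uniform(0, 2 * np.pi)
                xy[i] = [events[ev][2] + r * np.cos(th), events[ev][3] + r * np.sin(th)]
                pos = xy[i].copy()
            else:
                heading += rng.vonmises(0.0, config.turning_concentration)
                pos = pos + config.travel_step_m * np.array(
                    [np.cos(heading), np.sin(heading)]
                )
                xy[i] = pos
        # GPS collars report at whole-second resolution
        stamps = t0 + pd.to_timedelta(np.round(times * 86_400.0), unit="s")
        tracks.append(GpsTrack(animal_id=aid, timestamps=pd.DatetimeIndex(stamps), xy=xy))
        for (ts, handling, x, y) in events:
            kills.append(
                {
                    "animal_id": aid,
                    "kill_time": t0 + pd.Timedelta(days=ts),
                    "x": x,
                    "y": y,
                    "handling_days": handling,
                }
            )
    truth = pd.DataFrame(kills, columns=["animal_id", "kill_time", "x", "y", "handling_days"])
    return tracks, truth


def match_clusters_to_kills(
    clusters, truth: pd.DataFrame, radius: float = 200.0, time_slack_days: float = 1.0
) -> pd.DataFrame:
    """Greedy match of detected clusters to true kills (for recall/precision).

    A kill is recovered when some cluster of the same animal has its centroid
    within ``radius`` of the kill site and starts within ``time_slack_days``
    of the kill time.  Adds a boolean ``recovered`` column to the truth frame.
    """
    recovered = []
    for _, kill in truth.iterrows():
        hit = False
        for c in clusters:
            if c.animal_id != kill["animal_id"]:
                continue
            d = np.hypot(c.centroid[0] - kill["x"], c.centroid[1] - kill["y"])
            dt = abs((c.start - kill["kill_time"]).total_seconds()) / 86_400.0
            if d <= radius and dt <= time_slack_days + kill["handling_days"]:
                hit = True
                break
        recovered.append(hit)
    out = truth.copy()
    out["recovered"] = recovered
    return out


# ---------------------------------------------------------------------------
# Survival


def simulate_survival(
    config: SurvivalSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Tracking periods with exponential event times and uniform censoring."""
    start = pd.Timestamp(config.start_date)
    rows = []
    for group in sorted(config.n_per_group):
        n = config.n_per_group[group]
        hz = config.hazard_per_day[group]
        if hz < 0:
            raise ValueError("hazards must be non-negative")
        t_event = (
            rng.exponential(1.0 / hz, size=n) if hz > 0 else np.full(n, np.inf)
        )
        t_cens = rng.uniform(30.0, config.max_follow_up_days, size=n)
        time = np.minimum(t_event, t_cens)
        died = t_event <= t_cens
        for i in range(n):
            if died[i]:
                if rng.random() < config.natural_fraction.get(group, 0.0):
                    status = EndStatus.NATURAL_MORTALITY.value
                else:
                    status = rng.choice(
                        [
                            EndStatus.SUSPECTED_ILLEGAL_KILLING.value,
                            EndStatus.CONFIRMED_ILLEGAL_KILLING.value,
                            EndStatus.ROADKILL.value,
                        ],
                        p=[0.45, 0.45, 0.10],
                    )
            elif rng.random() < config.disappeared_fraction:
                status = EndStatus.DISAPPEARED.value
            else:
                status = EndStatus.ALIVE.value
            rows.append(
                {
                    "animal_id": f"{group[:2].upper()}{i:03d}",
                    "group": group,
                    "start": start,
                    "end": start + pd.Timedelta(days=float(time[i])),
                    "end_status": status,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle writer


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_all(config: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Generate all four data families, write CSVs + truth sidecars + manifest.

    Returns the manifest (relative path -> sha256), which is also written as
    ``manifest.json`` alongside a dump of the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table, truth_g = simulate_drift_population(config.drift, config.rng("drift"))
    lio.write_genotypes(table, outdir / "genotypes.csv")
    truth_g.to_csv(outdir / "genotypes_truth.csv", index=False)

    data, grid, truth_s = simulate_scr_dataset(config.scr, config.rng("scr"))
    lio.write_traps(data, outdir / "traps.csv")
    lio.write_detections(data, outdir / "detections.csv")
    grid.to_frame().to_csv(outdir / "state_space.csv", index=False)
    (outdir / "scr_truth.json").write_text(json.dumps(truth_s, indent=1))

    tracks, truth_k = simulate_tracks(config.tracks, config.rng("tracks"))
    lio.write_tracks(tracks, outdir / "tracks.csv")
    tk = truth_k.copy()
    if len(tk):
        tk["kill_time"] = tk["kill_time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    tk.to_csv(outdir / "kills_truth.csv", index=False)

    periods = simulate_survival(config.survival, config.rng("survival"))
    lio.write_periods(periods, outdir / "periods.csv")

    (outdir / "sim_config.json").write_text(json.dumps(asdict(config), indent=1))
    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json"))
        if p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
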