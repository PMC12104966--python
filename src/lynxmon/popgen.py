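"""Genetic monitoring of a reinforced population from microsatellite genotypes.

The module tracks the erosion and recovery of genetic diversity in a small,
founder-bottlenecked population that is being reinforced with translocated,
outbred immigrants.  Its currency is the diploid microsatellite genotype:
heterozygosity summaries (observed Ho, Nei's unbiased expected He), "effective
inbreeding" Fe = 1 - H_focal / H_reference measured against the source
population, the lethal-equivalents projection of inbreeding depression
(delta = 1 - exp(-B * Fe) with 2B diploid lethal equivalents), a traveling
(sliding) window that turns a chronologically ordered genotype series into an
Fe / fitness trajectory, reinforcement scenarios that select which animals the
trajectory may use, immigrant-ancestry detection through private alleles, and
parentage assignment by simple allele exclusion.

Genotypes are stored as integer allele identifiers with ``0`` meaning missing;
an allele pair is either both present or both missing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0

__all__ = [
    "MISSING",
    "Group",
    "Destination",
    "Scenario",
    "GenotypeTable",
    "WindowSeries",
    "ParentageResult",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "effective_inbreeding",
    "inbreeding_depression",
    "relative_fitness",
    "traveling_window",
    "scenario_series",
    "private_alleles",
    "flag_f1",
    "parentage_exclusion",
    "pair_parentage_exclusion",
]


class Group(str, Enum):
    """Demographic origin of a genotyped individual."""

    REMNANT = "remnant"
    TRANSLOCATED = "translocated"
    OFFSPRING_F1 = "offspring_f1"
    OFFSPRING_LATER = "offspring_later"
    UNKNOWN = "unknown"


class Destination(str, Enum):
    """Release destination of a translocated animal (or of its lineage)."""

    DINARIC = "dinaric"
    ALPINE_STEPPING_STONE = "alpine_stepping_stone"
    NONE = "none"


class Scenario(str, Enum):
    """Reinforcement scenarios: nested, growing subsets of the population.

    ``REMNANT_ONLY`` excludes the translocation entirely; ``DINARIC_REINFORCEMENT``
    adds animals translocated to the core (Dinaric) area and their offspring;
    ``FULLY_CONNECTED`` additionally merges the stepping-stone subpopulation.
    """

    REMNANT_ONLY = "remnant_only"
    DINARIC_REINFORCEMENT = "dinaric_reinforcement"
    FULLY_CONNECTED = "fully_connected"


class EmptyDataError(ValueError):
    """Raised when a computation receives no usable genotypes."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with dates and group labels.

    Parameters
    ----------
    meta
        One row per individual with columns ``individual_id`` (unique),
        ``sample_date`` (datetime-like), ``group`` and ``destination``
        (string values of :class:`Group` / :class:`Destination`).
    genotypes
        Integer array of shape ``(n_individuals, n_loci, 2)``; ``0`` = missing.
    locus_names
        Ordered locus labels, one per genotype column.
    """

    meta: pd.DataFrame
    genotypes: np.ndarray
    locus_names: list[str]

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, n_loci, 2)")
        if self.genotypes.shape[0] != len(self.meta):
            raise ValueError("meta and genotypes disagree on individual count")
        if self.genotypes.shape[1] != len(self.locus_names):
            raise ValueError("locus_names and genotypes disagree on locus count")
        ids = self.meta["individual_id"]
        if ids.duplicated().any():
            raise ValueError("individual_id must be unique within a table")
        half_missing = (self.genotypes == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("allele pairs must be both present or both missing")
        self.meta["sample_date"] = pd.to_datetime(self.meta["sample_date"])

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def subset(self, mask: np.ndarray | pd.Series) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.meta.loc[mask].reset_index(drop=True),
            self.genotypes[mask],
            list(self.locus_names),
        )

    def sort_chronologically(self) -> "GenotypeTable":
        """Order by sample date, ties broken by individual_id (reproducible)."""
        order = self.meta.sort_values(
            ["sample_date", "individual_id"], kind="mergesort"
        ).index.to_numpy()
        return GenotypeTable(
            self.meta.loc[order].reset_index(drop=True),
            self.genotypes[order],
            list(self.locus_names),
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[Mapping],
        locus_names: Sequence[str],
    ) -> "GenotypeTable":
        """Build a table from dict-like records with an ``alleles`` mapping."""
        records = list(records)
        meta = pd.DataFrame(
            {
                "individual_id": [r["individual_id"] for r in records],
                "sample_date": [r["sample_date"] for r in records],
                "group": [str(getattr(r.get("group", "unknown"), "value", r.get("group", "unknown"))) for r in records],
                "destination": [str(getattr(r.get("destination", "none"), "value", r.get("destination", "none"))) for r in records],
            }
        )
        geno = np.zeros((len(records), len(locus_names), 2), dtype=np.int64)
        for i, r in enumerate(records):
            for j, locus in enumerate(locus_names):
                pair = r["alleles"].get(locus)
                if pair is not None:
                    geno[i, j] = pair
        return cls(meta, geno, list(locus_names))


# ---------------------------------------------------------------------------
# Heterozygosity


def _typed_mask(genotypes: np.ndarray) -> np.ndarray:
    """(n, L) boolean: genotype present at locus."""
    return genotypes[..., 0] != MISSING


def observed_heterozygosity(table: GenotypeTable) -> tuple[pd.Series, float]:
    """Per-locus and mean observed heterozygosity Ho.

    Ho at a locus is the fraction of non-missing genotypes whose two alleles
    differ; the multi-locus value is the unweighted mean over loci with at
    least one typed genotype.
    """
    typed = _typed_mask(table.genotypes)
    if not typed.any():
        raise EmptyDataError("table contains no non-missing genotypes")
    het = (table.genotypes[..., 0] != table.genotypes[..., 1]) & typed
    n_typed = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_typed > 0, het.sum(axis=0) / np.maximum(n_typed, 1), np.nan)
    per_locus = pd.Series(ho, index=table.locus_names, name="ho")
    return per_locus, float(np.nanmean(ho))


def _locus_he(alleles: np.ndarray) -> float:
    """Nei's unbiased He from a flat array of allele calls (no missing)."""
    n = alleles.size // 2
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / alleles.size
    return (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p**2)))


def expected_heterozygosity(
    table: GenotypeTable, *, strict: bool = False
) -> tuple[pd.Series, float]:
    """Per-locus and mean Nei's unbiased expected heterozygosity.

    He_locus = 2n/(2n-1) * (1 - sum_i p_i^2) with ``n`` the count of typed
    genotypes at the locus and ``p_i`` the sample allele frequencies.  Loci
    with fewer than two typed genotypes are skipped (NaN) unless ``strict``,
    in which case they raise.
    """
    typed = _typed_mask(table.genotypes)
    if not typed.any():
        raise EmptyDataError("table contains no non-missing genotypes")
    he = np.full(table.n_loci, np.nan)
    for j in range(table.n_loci):
        alleles = table.genotypes[typed[:, j], j, :].ravel()
        if alleles.size < 4:  # fewer than two genotypes
            if strict:
                raise ValueError(
                    f"locus {table.locus_names[j]!r} has <2 typed genotypes"
                )
            continue
        he[j] = _locus_he(alleles)
    per_locus = pd.Series(he, index=table.locus_names, name="he")
    return per_locus, float(np.nanmean(he))


# ---------------------------------------------------------------------------
# Inbreeding and fitness projection


def effective_inbreeding(h_focal: float, h_reference: float) -> float:
    """Fe = 1 - H_focal / H_reference, the proportional heterozygosity loss.

    May be negative when the focal sample is more heterozygous than the
    reference; negative values are returned as-is so callers can flag them.
    """
    if h_reference <= 0:
        raise ValueError("reference heterozygosity must be positive")
    return 1.0 - h_focal / h_reference


def inbreeding_depression(
    fe: float, diploid_lethal_equivalents: float = 12.0
) -> float:
    """Expected inbreeding depression delta = 1 - exp(-(2B/2) * Fe).

    ``diploid_lethal_equivalents`` is 2B, the diploid genetic load; survival
    under load declines as exp(-B*Fe), so delta is the expected proportional
    fitness loss relative to the (outbred) reference population.
    """
    if fe < 0:
        raise ValueError("fe must be non-negative; clamp or reject upstream")
    if diploid_lethal_equivalents <= 0:
        raise ValueError("diploid lethal equivalents (2B) must be positive")
    return 1.0 - float(np.exp(-(diploid_lethal_equivalents / 2.0) * fe))


def relative_fitness(delta: float) -> float:
    """Remaining relative fitness 1 - delta."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    return 1.0 - delta


# ---------------------------------------------------------------------------
# Traveling window


@dataclass
class WindowSeries:
    """Ordered traveling-window statistics over a chronological genotype series."""

    frame: pd.DataFrame
    scenario: str | None = None
    member_ids: list[list[str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["scenario"] = self.scenario or ""
        out.to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> "WindowSeries":
        frame = pd.read_csv(path, parse_dates=["date_start", "date_end"])
        scenario = None
        if "scenario" in frame.columns:
            vals = frame["scenario"].dropna().unique()
            scenario = str(vals[0]) if len(vals) else None
            frame = frame.drop(columns=["scenario"])
        return WindowSeries(frame, scenario=scenario)


def traveling_window(
    table: GenotypeTable,
    h_reference: float = 0.592,
    width: int = 40,
    step: int = 1,
    lethal_equivalents: float = 12.0,
) -> WindowSeries:
    """Slide a fixed-size window through a chronologically ordered series.

    Window ``k`` covers individuals ``[k*step, k*step + width)`` after sorting
    by sample date (ties by id).  Each window reports He, Fe relative to
    ``h_reference``, the lethal-equivalents depression delta (computed on
    ``max(Fe, 0)``) and fitness ``1 - delta``.
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be positive")
    n = len(table)
    if n < width:
        raise EmptyDataError(f"need at least width={width} individuals, have {n}")
    ordered = table.sort_chronologically()
    rows = []
    members: list[list[str]] = []
    for k in range((n - width) // step + 1):
        lo = k * step
        win = ordered.subset(np.arange(lo, lo + width))
        _, he = expected_heterozygosity(win)
        fe = effective_inbreeding(he, h_reference)
        delta = inbreeding_depression(max(fe, 0.0), lethal_equivalents)
        rows.append(
            {
                "window_index": k,
                "date_start": win.meta["sample_date"].iloc[0],
                "date_end": win.meta["sample_date"].iloc[-1],
                "n": width,
                "he": he,
                "fe": fe,
                "fe_negative": fe < 0,
                "delta": delta,
                "fitness": 1.0 - delta,
            }
        )
        members.append(list(win.meta["individual_id"]))
    return WindowSeries(pd.DataFrame(rows), member_ids=members)


def _scenario_mask(meta: pd.DataFrame, scenario: Scenario) -> np.ndarray:
    group = meta["group"].astype(str)
    dest = meta["destination"].astype(str)
    remnant = group.isin([Group.REMNANT.value, Group.UNKNOWN.value])
    introduced = group.isin(
        [Group.TRANSLOCATED.value, Group.OFFSPRING_F1.value, Group.OFFSPRING_LATER.value]
    )
    if scenario is Scenario.REMNANT_ONLY:
        mask = remnant
    elif scenario is Scenario.DINARIC_REINFORCEMENT:
        mask = remnant | (introduced & (dest == Destination.DINARIC.value))
    elif scenario is Scenario.FULLY_CONNECTED:
        mask = remnant | introduced
    else:  # pragma: no cover - enum exhausts the choices
        raise ValueError(f"unknown scenario {scenario!r}")
    return mask.to_numpy()


def scenario_series(
    table: GenotypeTable,
    scenario: Scenario | str,
    h_reference: float = 0.592,
    width: int = 40,
    step: int = 1,
    lethal_equivalents: float = 12.0,
    excluded_ids: Iterable[str] = (),
) -> WindowSeries:
    """Traveling-window trajectory under one reinforcement scenario.

    ``excluded_ids`` removes translocated animals known to have died before
    reproduction or to have dispersed beyond the reach of potential mates;
    its membership is an explicit input because it comes from field records,
    not the genotypes.
    """
    scenario = Scenario(scenario)
    mask = _scenario_mask(table.meta, scenario)
    mask &= ~table.meta["individual_id"].isin(set(excluded_ids)).to_numpy()
    filtered = table.subset(mask)
    if len(filtered) < width:
        raise EmptyDataError(
            f"scenario {scenario.value!r} leaves {len(filtered)} individuals "
            f"(< width={width})"
        )
    series = traveling_window(
        filtered, h_reference, width=width, step=step,
        lethal_equivalents=lethal_equivalents,
    )
    series.scenario = scenario.value
    return series


# ---------------------------------------------------------------------------
# Private alleles and parentage


def private_alleles(
    reference: GenotypeTable, candidates: GenotypeTable
) -> dict[str, set[int]]:
    """Alleles carried by candidates but never seen in the reference sample.

    Returns a mapping locus -> set of private allele ids (possibly empty).
    Loci are matched by name; loci absent from either table are ignored.
    """
    if len(reference) == 0:
        raise EmptyDataError("reference table is empty")
    out: dict[str, set[int]] = {}
    for locus in candidates.locus_names:
        if locus not in reference.locus_names:
            continue
        jr = reference.locus_names.index(locus)
        jc = candidates.locus_names.index(locus)
        ref_alleles = set(reference.genotypes[:, jr, :].ravel()) - {MISSING}
        cand_alleles = set(candidates.genotypes[:, jc, :].ravel()) - {MISSING}
        out[locus] = cand_alleles - ref_alleles
    return out


def flag_f1(
    individual: Mapping[str, tuple[int, int]] | pd.Series,
    private: Mapping[str, set[int]],
) -> bool:
    """True iff the individual carries at least one private (immigrant) allele.

    ``individual`` maps locus -> allele pair (as produced by table iteration).
    """
    for locus, pair in dict(individual).items():
        priv = private.get(locus)
        if priv and (pair[0] in priv or pair[1] in priv):
            return True
    return False


@dataclass
class ParentageResult:
    """Outcome of exclusion-based parentage for one offspring."""

    offspring_id: str
    compatible_mothers: list[str]
    compatible_fathers: list[str]
    mismatch_counts: dict[str, int]
    compatible_pairs: list[tuple[str, str]] = field(default_factory=list)


def _single_parent_mismatches(
    off: np.ndarray, cand: np.ndarray
) -> int:
    """Loci where both are typed and the candidate shares no allele with offspring."""
    typed = (off[:, 0] != MISSING) & (cand[:, 0] != MISSING)
    share = (
        (cand[:, 0] == off[:, 0])
        | (cand[:, 0] == off[:, 1])
        | (cand[:, 1] == off[:, 0])
        | (cand[:, 1] == off[:, 1])
    )
    return int((typed & ~share).sum())


def _pair_locus_compatible(
    off: np.ndarray, mum: np.ndarray, dad: np.ndarray
) -> np.ndarray:
    """Per-locus: can the offspring alleles be partitioned one-from-each-parent?"""
    a, b = off[:, 0], off[:, 1]
    in_m = lambda x: (x == mum[:, 0]) | (x == mum[:, 1])  # noqa: E731
    in_d = lambda x: (x == dad[:, 0]) | (x == dad[:, 1])  # noqa: E731
    return (in_m(a) & in_d(b)) | (in_m(b) & in_d(a))


def parentage_exclusion(
    offspring_index: int | str,
    offspring_table: GenotypeTable,
    candidates: GenotypeTable,
    mismatch_tolerance: int = 0,
    candidate_sex: Mapping[str, str] | None = None,
) -> ParentageResult:
    """Assign possible parents to one offspring by simple allele exclusion.

    Single-parent test: a candidate is excluded when, at more than
    ``mismatch_tolerance`` jointly typed loci, it shares no allele with the
    offspring.  Pair test: a (mother, father) pair is compatible when at every
    jointly typed locus (allowing the same number of failures) the offspring's
    two alleles can be split one-from-each-parent.

    ``candidate_sex`` maps candidate id -> ``"female"``/``"male"``; without it
    every candidate is considered for both roles.
    """
    if isinstance(offspring_index, str):
        hits = np.flatnonzero(
            offspring_table.meta["individual_id"].to_numpy() == offspring_index
        )
        if hits.size == 0:
            raise KeyError(offspring_index)
        offspring_index = int(hits[0])
    off = offspring_table.genotypes[offspring_index]
    off_id = str(offspring_table.meta["individual_id"].iloc[offspring_index])
    if not (off[:, 0] != MISSING).any():
        raise EmptyDataError(f"offspring {off_id!r} has no typed loci")

    # align candidate loci to the offspring table's locus order
    common = [l for l in offspring_table.locus_names if l in candidates.locus_names]
    off_idx = [offspring_table.locus_names.index(l) for l in common]
    cand_idx = [candidates.locus_names.index(l) for l in common]
    off_g = off[off_idx]

    mism: dict[str, int] = {}
    singles: list[str] = []
    cand_ids = candidates.meta["individual_id"].astype(str).tolist()
    for i, cid in enumerate(cand_ids):
        if cid == off_id:
            continue
        m = _single_parent_mismatches(off_g, candidates.genotypes[i][cand_idx])
        mism[cid] = m
        if m <= mismatch_tolerance:
            singles.append(cid)

    def sex_of(cid: str) -> str:
        return (candidate_sex or {}).get(cid, "unknown")

    mothers = [c for c in singles if sex_of(c) in ("female", "unknown")]
    fathers = [c for c in singles if sex_of(c) in ("male", "unknown")]

    pairs: list[tuple[str, str]] = []
    for mid, fid in itertools.product(mothers, fathers):
        if mid == fid:
            continue
        mg = candidates.genotypes[cand_ids.index(mid)][cand_idx]
        fg = candidates.genotypes[cand_ids.index(fid)][cand_idx]
        typed = (
            (off_g[:, 0] != MISSING)
            & (mg[:, 0] != MISSING)
            & (fg[:, 0] != MISSING)
        )
        ok = _pair_locus_compatible(off_g, mg, fg)
        if int((typed & ~ok).sum()) <= mismatch_tolerance:
            pairs.append((mid, fid))

    return ParentageResult(
        offspring_id=off_id,
        compatible_mothers=mothers,
        compatible_fathers=fathers,
        mismatch_counts=mism,
        compatible_pairs=pairs,
    )


def pair_parentage_exclusion(
    offspring_index: int | str,
    offspring_table: GenotypeTable,
    candidates: GenotypeTable,
    mismatch_tolerance: int = 0,
    candidate_sex: Mapping[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Convenience wrapper returning only the compatible (mother, father) pairs."""
    return parentage_exclusion(
        offspring_index, offspring_table, candidates,
        mismatch_tolerance=mismatch_tolerance, candidate_sex=candidate_sex,
    ).compatible_pairs
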