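"""Synthetic claims cohort generator with planted co-prescription structure.

Real CHM claims data (national insurance reimbursement records) cannot be
redistributed, so every downstream stage of this package is exercised on
synthetic cohorts whose co-occurrence structure is *known*.  The generator
emulates the observable features of such data:

* prescriptions of ~6-7 items on average (target mean 6.2, unimodal);
* a catalog of herbal formulas (HF) and single herbs (SH) with marginal
  prevalences spanning ~1-30%;
* disjoint planted item clusters whose members co-occur more often than
  chance, organised around one high-prevalence anchor per cluster;
* one dominant hub item with elevated marginal prevalence;
* per-kind dose and duration scales (HF ~4 g/day, SH ~1-1.6 g/day,
  ~10-15 days per visit);
* optional decoy visits, each violating exactly one cohort-filter rule,
  so attrition counts are analytically predictable.

Sampling model (seeded-mixture Bernoulli).  For each prescription one
cluster is seeded with probability proportional to its ``seed_weight``
(or no cluster, with ``unseeded_weight``); every catalog item is then
included independently with probability ``q = b*o / (1 + b*o)`` where
``o`` is the item's calibrated base odds and ``b`` its cluster's
``within_cluster_boost`` if that cluster was seeded (else 1).  Empty
prescriptions are redrawn.  Consequences that the test-suite leans on:

* with all boosts equal to 1 items are *exactly* independent, so every
  pairwise lift converges to 1 — the independence limit of the planted
  structure;
* base odds are calibrated deterministically (per-item root finding, no
  simulation) so realized marginals match the targets regardless of
  boosts, which also pins the mean prescription size at the sum of the
  target marginals;
* within a seeded cluster all members are boosted simultaneously, which
  plants elevated co-occurrence (lift > 1) for every within-cluster pair
  and mild negative association across clusters.

The returned :class:`GroundTruth` (cluster memberships, boosted pairs,
intended marginals) is the recovery target for the mining and network
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .claims import HF, SH, CHMItem, Transaction, VisitRecord

__all__ = [
    "CatalogEntry",
    "SyntheticCohortSpec",
    "GroundTruth",
    "CalibrationReport",
    "default_catalog",
    "default_clusters",
    "default_spec",
    "generate_cohort",
    "calibration_report",
    "pairwise_lift_table",
]


@dataclass(frozen=True)
class CatalogEntry:
    """A catalog item with its intended marginal prevalence."""

    code: str
    name: str
    kind: str  # HF | SH
    prevalence: float  # target fraction of prescriptions containing the item

    def __post_init__(self) -> None:
        if not (0 < self.prevalence <= 1):
            raise ValueError(f"{self.code}: prevalence target must be in (0, 1]")
        if self.kind not in (HF, SH):
            raise ValueError(f"{self.code}: kind must be HF or SH")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """All generator parameters; fully determines the cohort given a seed.

    The marginal prevalence targets must sum to ``items_per_rx_mean``:
    every prescription's size is the sum of its item-inclusion
    indicators, so the sum of inclusion probabilities *is* the expected
    prescription size.  Specs violating this identity are rejected as
    infeasible before any sampling.
    """

    seed: int
    catalog: tuple[CatalogEntry, ...]
    clusters: tuple[frozenset[str], ...] = ()
    within_cluster_boost: tuple[float, ...] = ()  # odds factor per cluster, >= 1
    seed_weights: tuple[float, ...] = ()  # seeding propensity per cluster
    unseeded_weight: float = 0.05  # propensity of seeding no cluster
    hub_code: str | None = None
    n_patients: int = 1736
    n_visits: int | None = None  # exact visit total; overrides the patient draw
    visits_per_patient_mean: float = 7.5
    visits_per_patient_dispersion: float = 1.2
    items_per_rx_mean: float = 6.2
    # per-kind lognormal (mu of log, sigma of log) for dose g/day and duration days
    dose_model: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            HF: (np.log(4.2), 0.15, np.log(11.5), 0.22),
            SH: (np.log(1.25), 0.25, np.log(11.5), 0.22),
        }
    )
    decoy_fraction: float = 0.0
    start_date: date = date(2000, 1, 1)
    study_days: int = 2190  # six-year observation window

    def __post_init__(self) -> None:
        codes = [c.code for c in self.catalog]
        if len(set(codes)) != len(codes):
            raise ValueError("catalog codes must be unique")
        code_set = set(codes)
        seen: set[str] = set()
        for cl in self.clusters:
            if cl & seen:
                raise ValueError("clusters must be disjoint")
            if not cl <= code_set:
                raise ValueError("cluster members must be catalog codes")
            seen |= cl
        boosts = self.within_cluster_boost or tuple(1.0 for _ in self.clusters)
        if len(boosts) != len(self.clusters):
            raise ValueError("one boost per cluster required")
        if any(b < 1 for b in boosts):
            raise ValueError("within-cluster boost must be >= 1")
        object.__setattr__(self, "within_cluster_boost", tuple(boosts))
        weights = self.seed_weights or tuple(
            sum(e.prevalence for e in self.catalog if e.code in cl)
            for cl in self.clusters
        )
        if len(weights) != len(self.clusters):
            raise ValueError("one seed weight per cluster required")
        if any(w < 0 for w in weights) or self.unseeded_weight < 0:
            raise ValueError("seed weights must be nonnegative")
        object.__setattr__(self, "seed_weights", tuple(weights))
        if self.hub_code is not None and self.hub_code not in code_set:
            raise ValueError("hub_code must be a catalog code")
        if not (0 <= self.decoy_fraction < 1):
            raise ValueError("decoy_fraction must be in [0, 1)")
        target_sum = sum(e.prevalence for e in self.catalog)
        if abs(target_sum - self.items_per_rx_mean) > 0.05 * self.items_per_rx_mean:
            raise ValueError(
                "infeasible spec: marginal prevalence targets sum to "
                f"{target_sum:.3f}, but the expected prescription size equals "
                f"that sum and items_per_rx_mean is {self.items_per_rx_mean}"
            )

    def seeding_probabilities(self) -> np.ndarray:
        """P(seeded cluster = c) for c = 0..C-1, last entry = no cluster."""
        w = np.append(np.asarray(self.seed_weights, float), self.unseeded_weight)
        if w.sum() <= 0:
            out = np.zeros(len(w))
            out[-1] = 1.0
            return out
        return w / w.sum()

    def ground_truth(self) -> "GroundTruth":
        assignment: dict[str, int | None] = {e.code: None for e in self.catalog}
        pairs: set[frozenset[str]] = set()
        for cid, cl in enumerate(self.clusters, start=1):
            members = sorted(cl)
            for code in members:
                assignment[code] = cid
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pairs.add(frozenset((a, b)))
        return GroundTruth(
            cluster_assignment=assignment,
            planted_pairs=frozenset(pairs),
            marginals={e.code: e.prevalence for e in self.catalog},
            hub_code=self.hub_code,
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted — the recovery target for downstream stages."""

    cluster_assignment: Mapping[str, int | None]
    planted_pairs: frozenset[frozenset[str]]
    marginals: Mapping[str, float]
    hub_code: str | None = None


# ---------------------------------------------------------------------------
# default study conditions


def default_catalog(n_filler: int = 150) -> tuple[CatalogEntry, ...]:
    """Catalog of 21 named cluster items plus a long filler tail.

    Named items carry the prevalence scale of published utilization tables
    (hub formula at 28.1%, cluster anchors ~20%, companions 14-17%);
    filler herbs decay geometrically from ~3% down to ~1% and are scaled
    so all targets sum to the mean prescription size (a feasibility
    identity of the sampling model).  The 3% filler ceiling keeps every
    filler-item pair below a 1% co-occurrence support, so unplanted items
    cannot enter the mined combination tables.
    """
    named = [
        # cluster 1 — hub formula and companions
        CatalogEntry("GZFLW", "Gui-Zhi-Fu-Ling-Wan", HF, 0.281),
        CatalogEntry("JWXYS", "Jia-Wei-Xiao-Yao-San", HF, 0.172),
        CatalogEntry("SFZYT", "Shao-Fu-Zhu-Yu-Tang", HF, 0.140),
        CatalogEntry("LEON", "Leonurus heterophyllus", SH, 0.140),
        CatalogEntry("SALV", "Salvia miltiorrhiza", SH, 0.140),
        CatalogEntry("TAOR", "Prunus persica", SH, 0.140),
        # cluster 2
        CatalogEntry("CORY", "Corydalis yanhusuo", SH, 0.210),
        CatalogEntry("TYPH", "Typha angustifolia", SH, 0.140),
        CatalogEntry("TROG", "Trogopterus xanthipes", SH, 0.140),
        CatalogEntry("MELI", "Melia toosendan", SH, 0.140),
        # cluster 3
        CatalogEntry("CYPR", "Cyperus rotundus", SH, 0.210),
        CatalogEntry("CURC", "Curcuma phaeocaulis", SH, 0.140),
        CatalogEntry("SPAR", "Sparganium stoloniferum", SH, 0.140),
        # cluster 4
        CatalogEntry("DGSYS", "Dang-Gui-Shao-Yao-San", HF, 0.200),
        CatalogEntry("WJT", "Wen-Jing-Tang", HF, 0.140),
        CatalogEntry("ANGE", "Angelica sinensis", SH, 0.140),
        # cluster 5
        CatalogEntry("TARA", "Taraxacum mongolicum", SH, 0.200),
        CatalogEntry("CUSC", "Cuscuta chinensis", SH, 0.140),
        CatalogEntry("PAER", "Paeonia rubra", SH, 0.140),
        # cluster 6 — isolated couplet pair
        CatalogEntry("ECLI", "Eclipta prostrata", SH, 0.210),
        CatalogEntry("LIGU", "Ligustrum lucidum", SH, 0.140),
    ]
    remaining = 6.2 - sum(e.prevalence for e in named)
    decay = np.geomspace(1.0, 0.375, n_filler)
    decay *= remaining / decay.sum()
    fillers = [
        CatalogEntry(
            f"FIL{i:03d}",
            f"Filler herb {i:03d}",
            SH if i % 4 else HF,
            float(p),
        )
        for i, p in enumerate(decay)
    ]
    return tuple(named + fillers)


def default_clusters() -> tuple[frozenset[str], ...]:
    return (
        frozenset({"GZFLW", "JWXYS", "SFZYT", "LEON", "SALV", "TAOR"}),
        frozenset({"CORY", "TYPH", "TROG", "MELI"}),
        frozenset({"CYPR", "CURC", "SPAR"}),
        frozenset({"DGSYS", "WJT", "ANGE"}),
        frozenset({"TARA", "CUSC", "PAER"}),
        frozenset({"ECLI", "LIGU"}),
    )


def default_spec(
    seed: int,
    n_visits: int | None = None,
    boost: float = 8.0,
    decoy_fraction: float = 0.0,
) -> SyntheticCohortSpec:
    """The default study conditions: six planted clusters, one hub, boost 8."""
    clusters = default_clusters()
    return SyntheticCohortSpec(
        seed=seed,
        catalog=default_catalog(),
        clusters=clusters,
        within_cluster_boost=tuple(boost for _ in clusters),
        seed_weights=(0.20, 0.155, 0.155, 0.155, 0.155, 0.15),
        unseeded_weight=0.03,
        hub_code="GZFLW",
        n_visits=n_visits,
        decoy_fraction=decoy_fraction,
    )


# ---------------------------------------------------------------------------
# calibration and sampling


def _calibrate_inclusion_probs(spec: SyntheticCohortSpec) -> np.ndarray:
    """Per-(seeding-choice, item) inclusion probabilities hitting the targets.

    For each item, base odds ``o`` solve  p_target = sum_c P(c) * q(b_c o)
    with q(x) = x/(1+x) — a monotone scalar equation solved by bisection
    on log-odds.  Returns Q of shape (C+1, n_items); row C is the
    unseeded choice.  Deterministic; no simulation involved.
    """
    n_items = len(spec.catalog)
    n_clusters = len(spec.clusters)
    probs_c = spec.seeding_probabilities()
    code_index = {e.code: i for i, e in enumerate(spec.catalog)}
    # boost matrix b[c, i]: boost of item i under seeding choice c
    b = np.ones((n_clusters + 1, n_items))
    for cid, cl in enumerate(spec.clusters):
        for code in cl:
            b[cid, code_index[code]] = spec.within_cluster_boost[cid]
    targets = np.array([e.prevalence for e in spec.catalog])

    lo = np.full(n_items, -30.0)  # log-odds bracket
    hi = np.full(n_items, 30.0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        o = np.exp(mid)
        realized = probs_c @ ((b * o) / (1.0 + b * o))
        too_low = realized < targets
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    o = np.exp(0.5 * (lo + hi))
    return (b * o) / (1.0 + b * o)


def _sample_item_sets(
    spec: SyntheticCohortSpec,
    q_matrix: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n prescriptions; boolean (n, n_items) membership matrix.

    One seeding choice per prescription, then per-item inclusion at that
    choice's probabilities.  Both the seeding-class counts and each
    item's inclusion count within a class are balanced (floor(n*p) plus a
    randomized remainder, assigned to uniformly random rows): items stay
    independent given the class — co-occurrence is hypergeometric with
    the product mean — while realized marginals track the calibrated
    targets with only O(1/n) wiggle.  Empty prescriptions are redrawn
    with plain Bernoulli draws.
    """
    n_choices, n_items = q_matrix.shape
    # balanced seeding-class counts: floor + largest-remainder (randomized)
    raw = spec.seeding_probabilities() * n
    counts = np.floor(raw).astype(np.int64)
    deficit = int(n - counts.sum())
    if deficit > 0:
        rem = raw - counts
        keys = np.log(np.maximum(rem, 1e-300)) + rng.gumbel(size=n_choices)
        counts[np.argsort(keys)[-deficit:]] += 1
    seeded = rng.permutation(np.repeat(np.arange(n_choices), counts))

    chosen = np.zeros((n, n_items), dtype=bool)
    for c in range(n_choices):
        rows = np.flatnonzero(seeded == c)
        n_c = rows.size
        if n_c == 0:
            continue
        raw_m = q_matrix[c] * n_c
        m = np.floor(raw_m).astype(np.int64)
        m += rng.random(n_items) < (raw_m - m)
        # each column independently marks its m random rows
        keys = rng.random((n_c, n_items))
        rank = np.argsort(np.argsort(keys, axis=0, kind="stable"), axis=0)
        chosen[rows] = rank < m
    for _ in range(64):
        empty = ~chosen.any(axis=1)
        if not empty.any():
            break
        q = q_matrix[seeded[empty]]
        chosen[empty] = rng.random(q.shape) < q
    else:
        chosen[~chosen.any(axis=1), 0] = True  # pathological spec; keep non-empty
    return chosen


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[VisitRecord], GroundTruth]:
    """Generate a claims-style cohort; deterministic for a fixed spec.

    Every patient's first visit is a gynecology index visit carrying the
    disease code in the primary position, so with ``decoy_fraction = 0``
    the whole cohort passes the downstream filter cascade.  Decoy visits
    (``decoy_fraction`` of the core count, per violation type) each break
    exactly one rule — patient age out of range, disease code not in the
    primary position, or an excluded therapy on the visit — and are
    appended after the core visits.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    q_matrix = _calibrate_inclusion_probs(spec)

    # per-patient demographics and visit counts
    m, r = spec.visits_per_patient_mean, spec.visits_per_patient_dispersion
    n_pat = spec.n_patients
    counts = np.maximum(rng.negative_binomial(r, r / (r + m), size=n_pat), 1)
    if spec.n_visits is not None:
        while counts.sum() < spec.n_visits:
            extra = np.maximum(rng.negative_binomial(r, r / (r + m), size=n_pat), 1)
            counts = np.concatenate([counts, extra])
        owner = np.repeat(np.arange(counts.size), counts)[: spec.n_visits]
    else:
        owner = np.repeat(np.arange(n_pat), counts)
    n_core = owner.size
    n_pat_total = int(owner.max()) + 1

    age_at_start = rng.integers(22, 45, size=n_pat_total)
    birth_offset_days = rng.integers(0, 365, size=n_pat_total)
    visit_day = np.sort(rng.integers(0, spec.study_days, size=n_core))

    chosen = _sample_item_sets(spec, q_matrix, n_core, rng)

    kinds = np.array([e.kind for e in spec.catalog])
    codes = [e.code for e in spec.catalog]
    names = [e.name for e in spec.catalog]
    dose_mu = np.where(kinds == HF, spec.dose_model[HF][0], spec.dose_model[SH][0])
    dose_sig = np.where(kinds == HF, spec.dose_model[HF][1], spec.dose_model[SH][1])
    dur_mu = np.where(kinds == HF, spec.dose_model[HF][2], spec.dose_model[SH][2])
    dur_sig = np.where(kinds == HF, spec.dose_model[HF][3], spec.dose_model[SH][3])

    n_decoy = int(round(spec.decoy_fraction * n_core))
    decoy_kinds = ["age", "diagnosis", "therapy"]
    decoy_total = n_decoy * len(decoy_kinds)
    if decoy_total:
        decoy_owner = rng.integers(0, n_pat_total, size=decoy_total)
        decoy_day = rng.integers(0, spec.study_days, size=decoy_total)
        decoy_chosen = _sample_item_sets(spec, q_matrix, decoy_total, rng)

    # each patient's first core visit is the gynecology index visit
    first_visit_of: dict[int, int] = {}
    for i, pat in enumerate(owner):
        first_visit_of.setdefault(int(pat), i)

    def _build_visit(
        i: int, pat: int, day: int, row: np.ndarray, violation: str | None
    ) -> VisitRecord:
        birth = spec.start_date - timedelta(
            days=int(age_at_start[pat]) * 365 + int(birth_offset_days[pat])
        )
        vdate = spec.start_date + timedelta(days=int(day))
        if violation == "age":
            vdate = birth + timedelta(days=int(17.5 * 365))
        diagnoses = ["617.0"]
        if violation == "diagnosis":
            diagnoses = ["780.79", "617.0"]
        therapies = {"chm"}
        if violation == "therapy":
            therapies = {"chm", "acupuncture"}
        idx = np.flatnonzero(row)
        doses = np.exp(dose_mu[idx] + dose_sig[idx] * rng.standard_normal(idx.size))
        durs = np.clip(
            np.exp(dur_mu[idx] + dur_sig[idx] * rng.standard_normal(idx.size)),
            1.0,
            30.0,
        )
        items = [
            CHMItem(
                code=codes[j],
                name=names[j],
                kind=str(kinds[j]),
                dose_g_per_day=round(float(doses[t]), 2),
                duration_days=round(float(durs[t]), 1),
            )
            for t, j in enumerate(idx)
        ]
        return VisitRecord(
            patient_id=f"P{pat:06d}",
            visit_id=f"V{i:07d}",
            visit_date=vdate,
            patient_birth_date=birth,
            provider_specialty=(
                "gynecology" if first_visit_of.get(pat) == i else "tcm"
            ),
            diagnosis_codes=diagnoses,
            therapy_types=frozenset(therapies),
            items=items,
        )

    visits = [
        _build_visit(i, int(owner[i]), int(visit_day[i]), chosen[i], None)
        for i in range(n_core)
    ]
    if decoy_total:
        for t in range(decoy_total):
            violation = decoy_kinds[t // n_decoy]
            visits.append(
                _build_visit(
                    n_core + t,
                    int(decoy_owner[t]),
                    int(decoy_day[t]),
                    decoy_chosen[t],
                    violation,
                )
            )
    return visits, spec.ground_truth()


# ---------------------------------------------------------------------------
# calibration diagnostics


@dataclass(frozen=True)
class CalibrationReport:
    """Intended vs realized marginals and mean prescription size."""

    marginals: pd.DataFrame  # code, target, realized, se, z
    mean_items_target: float
    mean_items_realized: float
    mean_items_se: float

    @property
    def mean_items_z(self) -> float:
        return (self.mean_items_realized - self.mean_items_target) / self.mean_items_se

    @property
    def all_marginals_within_3se(self) -> bool:
        return bool((self.marginals["z"].abs() <= 3).all())


def calibration_report(
    visits: Sequence[VisitRecord], spec: SyntheticCohortSpec
) -> CalibrationReport:
    """Compare realized marginals and mean size with the spec's targets.

    Pass the core (non-decoy) visits: decoys are extra filter-bait visits
    outside the calibrated population.  The z columns are deviations in
    binomial standard errors at the given cohort size.
    """
    n = len(visits)
    if n == 0:
        raise ValueError("no visits to report on")
    counts = {e.code: 0 for e in spec.catalog}
    sizes = np.empty(n)
    for i, v in enumerate(visits):
        codes = v.item_codes
        sizes[i] = len(codes)
        for c in codes:
            if c in counts:
                counts[c] += 1
    rows = []
    for e in spec.catalog:
        realized = counts[e.code] / n
        se = float(np.sqrt(e.prevalence * (1 - e.prevalence) / n))
        rows.append(
            {
                "code": e.code,
                "target": e.prevalence,
                "realized": realized,
                "se": se,
                "z": (realized - e.prevalence) / se if se > 0 else 0.0,
            }
        )
    return CalibrationReport(
        marginals=pd.DataFrame(rows),
        mean_items_target=spec.items_per_rx_mean,
        mean_items_realized=float(sizes.mean()),
        mean_items_se=float(sizes.std(ddof=1) / np.sqrt(n)) if n > 1 else float("inf"),
    )


def pairwise_lift_table(
    transactions: Sequence[Transaction],
    codes: Sequence[str],
) -> pd.DataFrame:
    """Empirical lift for every pair among ``codes`` by direct counting.

    Independent of the Apriori path: co-occurrence counts come straight
    from a boolean membership matrix.  Used as the independence oracle for
    unboosted cohorts and for planted-structure checks.
    """
    n = len(transactions)
    idx = {c: i for i, c in enumerate(codes)}
    mat = np.zeros((n, len(codes)), dtype=bool)
    for r, t in enumerate(transactions):
        for c in t.items:
            j = idx.get(c)
            if j is not None:
                mat[r, j] = True
    p = mat.mean(axis=0)
    joint = (mat.T.astype(np.float64) @ mat.astype(np.float64)) / n
    rows = []
    for i, a in enumerate(codes):
        for j in range(i + 1, len(codes)):
            denom = p[i] * p[j]
            rows.append(
                {
                    "a": a,
                    "b": codes[j],
                    "support": joint[i, j],
                    "lift": joint[i, j] / denom if denom > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
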