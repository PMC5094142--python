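"""Synthetic road networks, cohorts and visit histories.

The generator emulates the data structure of an eleven-year county cohort of
asthma patients linked to a link-based traffic network:

* a planar road network — a rectangular grid of local streets forming an
  urban core in the centre of the extent, plus a small number of
  high-traffic arterials crossing the whole extent, with lognormal AADT
  draws whose tail reaches the busiest-segment counts of a mid-sized county
  seat (capped at 81,000 vehicles/day);
* a population whose sex split (44% male), age-band mixture, and block-group
  poverty mixture match the margins of such a cohort; high-poverty block
  groups sit adjacent to the arterials, most others in the urban core, and a
  rural fringe of block groups lies outside it (the emulated county is 83%
  urban); residences keep a minimum setback from road centrelines;
* visit histories in which each person's total exacerbation count is drawn
  Poisson with log-rate linear in log traffic density, sex, age, age^2 and
  block-group poverty, and each exacerbation is materialised as one of the
  three detectable event signatures (inpatient, ED, or an outpatient triple
  within 14 days).

Events and the two case-defining visits are placed in *disjoint 30-day slots*
within each person's residence window, so visits belonging to different
events are always more than 14 days apart: the cohort detector recovers the
generator's event list exactly, which is the round-trip contract the tests
rely on.  A ground-truth sidecar (coefficients actually used, materialised
event list) is produced for tests and never read by the pipeline proper.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .exposure import KernelSpec, RoadSegment, assign_exposures

logger = logging.getLogger("traffex")

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "generate_network",
    "generate_blockgroups",
    "generate_population",
    "generate_visits",
    "simulate",
]

SLOT_DAYS = 30  # > cluster window + max within-slot spread, so slots never interact
DAYS_PER_YEAR = 365.25

# cohort margins of the emulated study population (counts from an 11-year
# county asthma cohort of 19,915 patients)
MALE_FRACTION = 8785 / 19915
AGE_BANDS = ((0, 5), (5, 10), (10, 20), (20, 65), (65, 90))
AGE_BAND_WEIGHTS = (2853, 2272, 3953, 9436, 1401)
POVERTY_BANDS = ((0.0, 0.0), (1.0, 10.0), (11.0, 20.0), (20.0, 30.0), (30.0, 60.0))
POVERTY_BAND_WEIGHTS = (6, 72, 19, 1, 2)

AADT_CAP = 81_000.0  # busiest observed roadway segment in the study county

ASTHMA_CODES = ("493.00", "493.01", "493.90", "493.92")
OTHER_CODES = ("465.9", "250.00", "401.9", "786.2", "382.9", "780.60")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    The exacerbation log-rate for a person is

        eta = beta0 + beta_log_density * ln(density)
              + beta_sex * male + beta_age * age + beta_age2 * age^2
              + beta_poverty * poverty_index

    and the total event count over the residence window is drawn
    Poisson(person_years * baseline_rate * exp(eta)).  ``beta0=None`` asks the
    generator to centre the linear predictor so the cohort mean of exp(eta)
    is 1, making ``baseline_rate`` the cohort-mean event rate in
    events/person-year.

    Default effect sizes correspond to the observed per-10%-traffic ratios of
    the emulated study: exp(beta_log_density * ln 1.1) = 1.15.
    """

    seed: int = 0
    n_persons: int = 2000
    study_start: date = date(2000, 1, 1)
    study_end: date = date(2010, 12, 31)
    grid_extent: float = 5000.0
    core_fraction: float = 0.6
    rural_fraction: float = 0.17
    residence_setback: float = 25.0
    n_grid: int = 6
    n_arterials: int = 3
    arterial_aadt: float = 30_000.0
    collector_aadt: float = 6_000.0
    local_aadt: float = 800.0
    n_blockgroups: int = 30
    beta0: float | None = None
    beta_log_density: float = float(np.log(1.15) / np.log(1.1))
    beta_sex: float = float(np.log(1.29))
    beta_age: float = 0.02
    beta_age2: float = -0.0005
    beta_poverty: float = float(np.log(1.02))
    baseline_rate: float = 0.065
    background_visit_rate: float = 0.8
    p_inpatient: float = 0.10
    p_ed: float = 0.30
    p_outpatient: float = 0.60
    kernel: KernelSpec = field(default_factory=KernelSpec)
    cell_size: float = 50.0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        if min(self.arterial_aadt, self.local_aadt) <= 0:
            raise ValueError("AADT parameters must be positive")
        if self.grid_extent <= 0:
            raise ValueError("grid_extent must be positive")
        mix = self.p_inpatient + self.p_ed + self.p_outpatient
        if abs(mix - 1.0) > 1e-9:
            raise ValueError("event-type mixture must sum to 1")

    @property
    def study_years(self) -> int:
        """Whole calendar years spanned by the study window."""
        return self.study_end.year - self.study_start.year + 1


@dataclass
class SimulationResult:
    """All artefacts of one simulated study."""

    config: SimulationConfig
    network: list[RoadSegment]
    block_groups: pd.DataFrame
    persons: pd.DataFrame
    visits: pd.DataFrame
    exposures: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# Road network
# ---------------------------------------------------------------------------

def generate_network(
    config: SimulationConfig, rng: np.random.Generator
) -> list[RoadSegment]:
    """A rectangular grid of local streets plus high-AADT arterials.

    The grid has ``n_grid`` x ``n_grid`` intersections (2 n (n-1) street
    segments) occupying the central ``core_fraction`` of the extent (the
    urban core), with a road hierarchy: every other grid line is a collector
    street (intermediate traffic), the rest are local streets.  Each arterial
    crosses the *full* extent, alternating horizontal/vertical, offset from
    the grid lines.  AADT values are lognormal draws around the configured
    means, capped at 81,000 (the busiest-segment count of the emulated
    county).
    """
    if config.grid_extent <= 0:
        raise ValueError("grid_extent must be positive")
    n = config.n_grid
    lo = 0.5 * (1.0 - config.core_fraction) * config.grid_extent
    hi = config.grid_extent - lo
    coords = np.linspace(lo, hi, n)
    segments: list[RoadSegment] = []
    k = 0

    def draw_aadt(mean: float, sigma: float) -> float:
        val = float(rng.lognormal(np.log(mean) - sigma**2 / 2.0, sigma))
        return min(val, AADT_CAP)

    def street_mean(line_index: int) -> float:
        return config.collector_aadt if line_index % 2 == 0 else config.local_aadt

    for i in range(n):  # horizontal streets (collector/local alternating)
        for j in range(n - 1):
            v = np.array([[coords[j], coords[i]], [coords[j + 1], coords[i]]])
            segments.append(RoadSegment(f"L{k:04d}", v, draw_aadt(street_mean(i), 0.5)))
            k += 1
    for i in range(n):  # vertical streets
        for j in range(n - 1):
            v = np.array([[coords[i], coords[j]], [coords[i], coords[j + 1]]])
            segments.append(RoadSegment(f"L{k:04d}", v, draw_aadt(street_mean(i), 0.5)))
            k += 1
    for a in range(config.n_arterials):
        off = float(rng.uniform(0.35, 0.65)) * config.grid_extent
        if a % 2 == 0:
            v = np.array([[0.0, off], [config.grid_extent, off]])
        else:
            v = np.array([[off, 0.0], [off, config.grid_extent]])
        segments.append(
            RoadSegment(f"A{a:02d}", v, draw_aadt(config.arterial_aadt, 0.3))
        )
    return segments


# ---------------------------------------------------------------------------
# Block groups and population
# ---------------------------------------------------------------------------

def generate_blockgroups(
    config: SimulationConfig, network: list[RoadSegment], rng: np.random.Generator
) -> pd.DataFrame:
    """Block groups with a poverty index and a placement centre.

    Poverty indices are drawn from a banded mixture (most mass in the 1-10%
    band).  The highest-poverty third of block groups is centred 100-400 m
    from a random point on an arterial inside the urban core, emulating
    low-income housing concentrated adjacent to high-traffic corridors; of
    the rest, a rural fraction is uniform over the whole extent and the
    remainder uniform within the core.
    """
    m = config.n_blockgroups
    bands = rng.choice(len(POVERTY_BANDS), size=m, p=np.asarray(POVERTY_BAND_WEIGHTS) / 100.0)
    poverty = np.array(
        [rng.uniform(*POVERTY_BANDS[b]) if POVERTY_BANDS[b][1] > 0 else 0.0 for b in bands]
    )
    arterials = [s for s in network if s.id.startswith("A")]
    core_lo = 0.5 * (1.0 - config.core_fraction) * config.grid_extent
    core_hi = config.grid_extent - core_lo
    centers = np.empty((m, 2))
    order = np.argsort(-poverty)
    n_near = m // 3
    for rank, i in enumerate(order):
        if rank < n_near and arterials:
            art = arterials[rng.integers(len(arterials))]
            t = rng.uniform(0.3, 0.7)  # stretch of the arterial inside town
            pt = art.vertices[0] + t * (art.vertices[-1] - art.vertices[0])
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(100.0, 400.0)
            centers[i] = pt + dist * np.array([np.cos(ang), np.sin(ang)])
        elif rng.random() < config.rural_fraction:
            centers[i] = rng.uniform(0.02, 0.98, size=2) * config.grid_extent
        else:
            centers[i] = rng.uniform(core_lo, core_hi, size=2)
    centers = np.clip(centers, 0.02 * config.grid_extent, 0.98 * config.grid_extent)
    return pd.DataFrame(
        {
            "block_group_id": [f"BG{i:03d}" for i in range(m)],
            "poverty_index": np.round(poverty, 2),
            "center_x": np.round(centers[:, 0], 2),
            "center_y": np.round(centers[:, 1], 2),
        }
    )


def generate_population(
    config: SimulationConfig,
    network: list[RoadSegment],
    block_groups: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the study cohort.

    Sex is Bernoulli(0.44 male); ages come from a banded mixture matching the
    emulated cohort's age distribution; each person is assigned a block group
    uniformly and placed Gaussian (sd 150 m) around its centre, clipped to
    the extent and kept at least ``residence_setback`` metres from every road
    centreline (homes do not sit on the carriageway); person-years of
    residence are integers in [1, study span], with just over half the cohort
    resident the whole window.
    """
    if not network:
        raise ValueError("network must be non-empty")
    n = config.n_persons
    male = rng.random(n) < MALE_FRACTION
    bands = rng.choice(
        len(AGE_BANDS), size=n, p=np.asarray(AGE_BAND_WEIGHTS) / sum(AGE_BAND_WEIGHTS)
    )
    lo = np.array([AGE_BANDS[b][0] for b in bands], dtype=float)
    hi = np.array([AGE_BANDS[b][1] for b in bands], dtype=float)
    age = np.round(lo + rng.random(n) * (hi - lo), 1)
    bg_idx = rng.integers(len(block_groups), size=n)
    centers = block_groups[["center_x", "center_y"]].to_numpy(float)[bg_idx]
    xy = centers + rng.normal(0.0, 150.0, size=(n, 2))
    xy = np.clip(xy, 0.0, config.grid_extent)
    # enforce the setback by resampling the jitter for offending residences
    seg_a = np.vstack([s.vertices[:-1] for s in network])
    seg_b = np.vstack([s.vertices[1:] for s in network])
    for _ in range(30):
        too_close = _dist_to_segments(xy, seg_a, seg_b) < config.residence_setback
        if not too_close.any():
            break
        k = int(too_close.sum())
        xy[too_close] = np.clip(
            centers[too_close] + rng.normal(0.0, 150.0, size=(k, 2)),
            0.0,
            config.grid_extent,
        )
    # any stragglers are nudged radially off the nearest segment
    close = _dist_to_segments(xy, seg_a, seg_b) < config.residence_setback
    if close.any():
        xy[close] = xy[close] + config.residence_setback
    span = config.study_years
    full = rng.random(n) < 0.55
    py = np.where(full, span, rng.integers(1, span, size=n))
    return pd.DataFrame(
        {
            "person_id": [f"P{i:06d}" for i in range(n)],
            "sex": np.where(male, "male", "female"),
            "age": age,
            "x_m": np.round(xy[:, 0], 2),
            "y_m": np.round(xy[:, 1], 2),
            "block_group_id": block_groups["block_group_id"].to_numpy()[bg_idx],
            "poverty_index": block_groups["poverty_index"].to_numpy(float)[bg_idx],
            "person_years": py.astype(int),
        }
    )


def _dist_to_segments(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest of the straight segments a->b."""
    d = b - a  # (m, 2)
    L2 = np.einsum("ij,ij->i", d, d)
    L2 = np.where(L2 > 0, L2, 1.0)
    # t[i, j]: projection of point i on segment j, clipped to the segment
    diff = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("pmk,mk->pm", diff, d) / L2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return dist.min(axis=1)


# ---------------------------------------------------------------------------
# Visit histories
# ---------------------------------------------------------------------------

def _floor_positive(values: np.ndarray) -> np.ndarray:
    """Replace non-positive values by half the minimum positive value."""
    values = np.asarray(values, dtype=float)
    pos = values[values > 0]
    if len(pos) == 0:
        raise ValueError("no positive values to derive a log floor from")
    return np.where(values > 0, values, pos.min() / 2.0)


def _linear_predictor(
    persons: pd.DataFrame, density: np.ndarray, config: SimulationConfig
) -> tuple[np.ndarray, float]:
    male = (persons["sex"] == "male").to_numpy(float)
    age = persons["age"].to_numpy(float)
    pov = persons["poverty_index"].to_numpy(float)
    core = (
        config.beta_log_density * np.log(density)
        + config.beta_sex * male
        + config.beta_age * age
        + config.beta_age2 * age**2
        + config.beta_poverty * pov
    )
    if config.beta0 is None:
        # centre so the cohort-mean relative rate exp(eta) is 1, making
        # baseline_rate the arithmetic-mean event rate per person-year
        beta0 = -float(np.log(np.exp(core - core.max()).mean()) + core.max())
    else:
        beta0 = config.beta0
    return beta0 + core, beta0


def generate_visits(
    persons: pd.DataFrame,
    exposures: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Materialise visit histories and the ground-truth sidecar.

    Each person's event count is Poisson(person_years * baseline_rate *
    exp(eta)); every drawn event becomes one of the three detectable
    signatures, assigned to its own 30-day slot inside the person's residence
    window.  Two case-defining outpatient visits (first-dx asthma, <= 548
    days apart) and Poisson background non-asthma visits are added.

    Returns ``(visits, truth)``; ``truth`` holds the resolved coefficients
    and the materialised event list (person_id, date ISO, kind) that the
    cohort detector must recover exactly.
    """
    expo = exposures.set_index("person_id")
    missing = [p for p in persons["person_id"] if p not in expo.index]
    if missing:
        raise KeyError(f"no exposure record for person(s): {missing[:5]}")
    density = _floor_positive(
        expo.loc[persons["person_id"], "density"].to_numpy(float)
    )
    eta, beta0 = _linear_predictor(persons, density, config)
    py = persons["person_years"].to_numpy(int)
    lam = py * config.baseline_rate * np.exp(eta)
    counts = rng.poisson(lam)

    start = np.datetime64(config.study_start, "D")
    mixture = np.array([config.p_inpatient, config.p_ed, config.p_outpatient])
    kinds = np.array(["hospitalization", "ed_visit", "outpatient_cluster"])

    rows: list[tuple] = []  # person_id, date(int day offset), setting, dx1, dx2, dx3
    truth_events: list[tuple[str, str, str]] = []
    n_clamped = 0

    def other_dx(k: int) -> list[str]:
        picks = rng.choice(len(OTHER_CODES), size=k)
        return [OTHER_CODES[i] for i in picks]

    for i, pid in enumerate(persons["person_id"]):
        n_slots = int(py[i] * DAYS_PER_YEAR // SLOT_DAYS)
        n_events = int(counts[i])
        if n_events > n_slots - 2:
            n_clamped += 1
            n_events = n_slots - 2
        counts[i] = n_events

        # choose disjoint slots: events + two case-defining visits
        slots = rng.permutation(n_slots)
        event_slots = slots[:n_events]
        # the case pair must fall within 548 days (<= 17 slots apart); if no
        # such pair of free slots exists, both visits share one slot
        free = np.sort(slots[n_events:])
        gaps = np.diff(free)
        close = np.flatnonzero(gaps <= 17)
        if len(close):
            j = int(close[rng.integers(len(close))])
            case_days = [
                int(free[j]) * SLOT_DAYS + int(rng.integers(0, CLUSTER_DAYS_IN_SLOT)),
                int(free[j + 1]) * SLOT_DAYS + int(rng.integers(0, CLUSTER_DAYS_IN_SLOT)),
            ]
        else:
            offs = rng.choice(CLUSTER_DAYS_IN_SLOT, size=2, replace=False)
            case_days = [int(free[0]) * SLOT_DAYS + int(o) for o in offs]

        ev_kinds = kinds[rng.choice(3, size=n_events, p=mixture)]
        for slot, kind in zip(event_slots, ev_kinds):
            base = int(slot) * SLOT_DAYS
            if kind == "hospitalization":
                day = base + int(rng.integers(0, CLUSTER_DAYS_IN_SLOT))
                rows.append((pid, day, "inpatient", _pick(rng, ASTHMA_CODES), *other_dx(2)))
                ev_day = day
            elif kind == "ed_visit":
                day = base + int(rng.integers(0, CLUSTER_DAYS_IN_SLOT))
                rows.append((pid, day, "ed", _pick(rng, ASTHMA_CODES), *other_dx(2)))
                ev_day = day
            else:
                offs = np.sort(rng.choice(CLUSTER_DAYS_IN_SLOT, size=3, replace=False))
                for o in offs:
                    pos = rng.choice(3, p=[0.5, 0.3, 0.2])
                    dx = other_dx(3)
                    dx[pos] = _pick(rng, ASTHMA_CODES)
                    rows.append((pid, base + int(o), "outpatient", *dx))
                ev_day = base + int(offs[0])
            truth_events.append(
                (pid, str(start + np.timedelta64(ev_day, "D")), kind)
            )

        for day in case_days:  # case-defining singletons, first-dx asthma
            rows.append((pid, day, "outpatient", _pick(rng, ASTHMA_CODES), *other_dx(2)))

        # background non-asthma visits anywhere in the residence window
        n_bg = int(rng.poisson(config.background_visit_rate * py[i]))
        bg_days = rng.integers(0, int(py[i] * DAYS_PER_YEAR), size=n_bg)
        bg_settings = np.array(["outpatient", "ed", "inpatient"])[
            rng.choice(3, size=n_bg, p=[0.85, 0.10, 0.05])
        ]
        for day, setting in zip(bg_days, bg_settings):
            rows.append((pid, int(day), setting, *other_dx(3)))

    visits = pd.DataFrame(
        rows, columns=["person_id", "day", "setting", "dx1", "dx2", "dx3"]
    )
    visits["date"] = start + visits.pop("day").to_numpy("timedelta64[D]")
    visits["date"] = pd.to_datetime(visits["date"])
    visits = visits[["person_id", "date", "setting", "dx1", "dx2", "dx3"]]
    visits = visits.sort_values(["person_id", "date", "setting"], kind="stable").reset_index(
        drop=True
    )
    if n_clamped:
        logger.warning("event counts clamped to available slots for %d persons", n_clamped)
    truth = {
        "coefficients": {
            "beta0": beta0,
            "beta_log_density": config.beta_log_density,
            "beta_sex": config.beta_sex,
            "beta_age": config.beta_age,
            "beta_age2": config.beta_age2,
            "beta_poverty": config.beta_poverty,
            "baseline_rate": config.baseline_rate,
        },
        "n_events_total": int(counts.sum()),
        "event_counts": {
            pid: int(c) for pid, c in zip(persons["person_id"], counts)
        },
        "events": sorted(truth_events),
        "n_clamped": n_clamped,
    }
    return visits, truth


CLUSTER_DAYS_IN_SLOT = 14  # visits occupy days 0..13 of a slot; slots are 30 d


def _pick(rng: np.random.Generator, codes: tuple[str, ...]) -> str:
    return codes[int(rng.integers(len(codes)))]


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the whole generator: network, block groups, cohort, exposures, visits.

    Deterministic: a fixed config (including its seed) yields byte-identical
    output tables.
    """
    rng = np.random.default_rng(config.seed)
    network = generate_network(config, rng)
    block_groups = generate_blockgroups(config, network, rng)
    persons = generate_population(config, network, block_groups, rng)
    exposures, _rejects = assign_exposures(
        persons, network, kernel=config.kernel, cell_size=config.cell_size
    )
    visits, truth = generate_visits(persons, exposures, config, rng)
    truth["config"] = {
        k: (str(v) if isinstance(v, date) else v)
        for k, v in dataclasses.asdict(config).items()
        if not isinstance(v, dict)
    }
    return SimulationResult(
        config=config,
        network=network,
        block_groups=block_groups,
        persons=persons,
        visits=visits,
        exposures=exposures,
        truth=truth,
    )
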