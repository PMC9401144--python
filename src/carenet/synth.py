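"""Synthetic claims generator with planted cooperation structure.

Emulates the statistical regime of femoral-neck-fracture claims data from a
single Japanese prefecture: per-patient fracture histories with exponential
inter-fracture gaps (mean 126 days), acute -> recovery hospital transfers,
pre/post-hospitalization outpatient care on a weekly lattice, and
area-clustered patient sharing among providers.  Each provider carries a
latent "cooperation level"; providers with higher cooperation share patients
with more partners, and hospital stays shorten with the cooperation of the
providers involved.  The planted quantities are returned as a
:class:`GroundTruth` so downstream estimators can be checked for recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "ClaimRecord",
    "CLAIMS_COLUMNS",
    "generate_providers",
    "generate_patients",
    "generate_claims",
    "simulate",
    "write_claims",
    "read_claims",
    "claims_to_records",
    "records_to_claims",
]

#: Canonical column order of the claims CSV schema.
CLAIMS_COLUMNS = [
    "patient_id",
    "provider_id",
    "record_type",
    "admission_date",
    "discharge_date",
    "visit_date",
    "surgery_date",
    "age",
    "sex",
    "in_prefecture",
]

MEAN_AGE = 83.2  # cohort mean age at admission (elderly fracture patients)


def _area_centers(n_areas: int) -> tuple[np.ndarray, np.ndarray]:
    ang = 2.0 * np.pi * np.arange(n_areas) / n_areas
    return 10.0 * np.cos(ang), 10.0 * np.sin(ang)


class ConfigError(ValueError):
    """Raised when a SynthConfig field is out of range."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic claims world.

    Defaults define the package's reference study conditions: 1800 patients
    over a six-year horizon, five medical administration areas, a fracture
    rate giving roughly two thousand analyzable surgical cases, ~80% of
    hospitalizations without transfer, and a negative planted effect of
    provider cooperation on the duration of hospital stay.
    """

    n_patients: int = 1800
    n_providers: int = 220
    n_areas: int = 5
    #: proportions of acute / recovery / outpatient-clinic providers
    provider_roles: tuple[float, float, float] = (0.22, 0.23, 0.55)
    #: inclusive bed-count range per role (acute, recovery, outpatient)
    beds_range: tuple[tuple[int, int], ...] = ((100, 600), (50, 300), (0, 19))
    fracture_rate: float = 1.2  # expected fractures per patient over horizon
    #: geographic scale: providers and patients scatter (sd) around their
    #: area center; choice decays over sigma_clinic / sigma_hospital
    geo_spread: float = 4.0
    sigma_clinic: float = 0.8
    sigma_hospital: float = 4.0
    horizon: tuple[str, str] = ("2014-01-01", "2019-12-31")
    transfer_prob: float = 0.19
    mean_interfracture_days: float = 126.0
    outpatient_cycle_days: int = 7
    stay_base: float = 62.0
    coop_effect: float = -12.0  # days per unit of standardized log-cooperation
    age_effect: float = 0.26  # days per year of age
    noise_sd: float = 15.0
    nonlinearity: bool = False
    surgery_prob: float = 0.96
    within_area_prob: float = 0.9
    out_of_prefecture_frac: float = 0.10
    #: rate tying the number of distinct outpatient partners per case to the
    #: (relative) cooperation level of the admitting hospital
    partner_rate: float = 1.2
    heavy_tail_prob: float = 0.015
    #: quiet days after the last care contact before fracture recurrence can
    #: begin; keeps distinct fractures from chaining through the tau2 rule
    refracture_buffer_days: float = 35.0
    seed: int = 0

    def validate(self) -> "SynthConfig":
        for name in ("transfer_prob", "surgery_prob", "within_area_prob",
                     "out_of_prefecture_frac", "heavy_tail_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_areas < 1:
            raise ConfigError(f"n_areas must be >= 1, got {self.n_areas}")
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.n_providers < 1:
            raise ConfigError(f"n_providers must be >= 1, got {self.n_providers}")
        if abs(sum(self.provider_roles) - 1.0) > 1e-9:
            raise ConfigError("provider_roles must sum to 1")
        if any(p < 0 for p in self.provider_roles):
            raise ConfigError("provider_roles must be non-negative")
        start, end = (date.fromisoformat(d) for d in self.horizon)
        if end < start:
            raise ConfigError(f"horizon is empty: {self.horizon}")
        if self.mean_interfracture_days <= 0:
            raise ConfigError("mean_interfracture_days must be positive")
        if self.fracture_rate <= 0:
            raise ConfigError("fracture_rate must be positive")
        if self.outpatient_cycle_days < 1:
            raise ConfigError("outpatient_cycle_days must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        return self

    @property
    def horizon_dates(self) -> tuple[date, date]:
        return tuple(date.fromisoformat(d) for d in self.horizon)  # type: ignore[return-value]


@dataclass
class GroundTruth:
    """Planted quantities of a simulation, the oracle for recovery tests."""

    provider_coop: dict[str, float] = field(default_factory=dict)
    provider_area: dict[str, int] = field(default_factory=dict)
    provider_community: dict[str, int] = field(default_factory=dict)
    #: per-community additive stay offset (days), active when nonlinearity=True
    community_offset: dict[int, float] = field(default_factory=dict)
    #: one row per generated fracture case (expected-stay decomposition)
    case_effects: pd.DataFrame | None = None
    #: every drawn inter-fracture gap (days), including ones whose fracture
    #: fell beyond the horizon and produced no claims
    interfracture_gaps: list[float] = field(default_factory=list)


@dataclass
class ClaimRecord:
    """One inpatient or outpatient billing line."""

    patient_id: str
    provider_id: str
    record_type: str  # "inpatient" | "outpatient"
    admission_date: date | None = None
    discharge_date: date | None = None
    visit_date: date | None = None
    surgery_date: date | None = None
    age: int = 0
    sex: str = "female"
    in_prefecture: bool = True

    def __post_init__(self) -> None:
        if self.record_type == "inpatient":
            if self.admission_date is None or self.discharge_date is None:
                raise ValueError("inpatient record requires admission and discharge dates")
            if self.visit_date is not None:
                raise ValueError("inpatient record must not carry a visit date")
            if self.discharge_date < self.admission_date:
                raise ValueError(
                    f"discharge {self.discharge_date} precedes admission {self.admission_date}"
                )
            if self.surgery_date is not None and not (
                self.admission_date <= self.surgery_date <= self.discharge_date
            ):
                raise ValueError("surgery date outside the stay")
        elif self.record_type == "outpatient":
            if self.visit_date is None:
                raise ValueError("outpatient record requires a visit date")
            if (self.admission_date is not None or self.discharge_date is not None
                    or self.surgery_date is not None):
                raise ValueError("outpatient record carries inpatient-only fields")
        else:
            raise ValueError(f"unknown record_type: {self.record_type!r}")


# ---------------------------------------------------------------------------
# generation


def _role_counts(config: SynthConfig) -> np.ndarray:
    raw = np.array(config.provider_roles) * config.n_providers
    counts = np.floor(raw).astype(int)
    # distribute the remainder to the largest fractional parts, deterministically
    rem = config.n_providers - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_providers(
    config: SynthConfig, rng_seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Create the provider table and its planted ground truth.

    Each provider gets a medical administration area (the planted community),
    a role (acute / recovery / outpatient clinic), a bed count, an
    in-prefecture flag and a positive latent cooperation level drawn
    log-normally around an area-specific mean, so areas differ in their
    typical cooperation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)

    n = config.n_providers
    roles = np.repeat(["acute", "recovery", "outpatient"], _role_counts(config))
    # areas assigned role-stratified round-robin so every area gets all roles
    areas = np.empty(n, dtype=int)
    for role in ("acute", "recovery", "outpatient"):
        idx = np.where(roles == role)[0]
        areas[idx] = np.arange(len(idx)) % config.n_areas
    beds = np.empty(n, dtype=int)
    for r, (lo, hi) in zip(("acute", "recovery", "outpatient"), config.beds_range):
        mask = roles == r
        beds[mask] = rng.integers(lo, hi + 1, size=mask.sum())

    in_pref = rng.random(n) >= config.out_of_prefecture_frac
    # areas sit on a ring; providers scatter around their area center, which
    # makes patient sharing geographically local (area-clustered network)
    cx, cy = _area_centers(config.n_areas)
    px = cx[areas] + rng.normal(0.0, config.geo_spread, size=n)
    py = cy[areas] + rng.normal(0.0, config.geo_spread, size=n)
    # cooperation varies smoothly across geography (neighbouring providers
    # share referral infrastructure): an area-level mean plus a low-frequency
    # spatial field plus a small provider-specific residual
    area_coop_mu = rng.normal(0.0, 0.25, size=config.n_areas)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=2)
    spatial = 0.4 * (np.sin(0.3 * px + phase[0]) + np.cos(0.3 * py + phase[1]))
    coop = np.exp(area_coop_mu[areas] + spatial + rng.normal(0.0, 0.15, size=n))
    # community-level stay offsets (active in the nonlinear regime) scale
    # with the cooperation effect so the multi-dimensional component is
    # commensurate with the scalar one
    community_offset = rng.normal(0.0, abs(config.coop_effect), size=config.n_areas)

    ids = [f"m{i:04d}" for i in range(n)]
    providers = pd.DataFrame(
        {
            "provider_id": ids,
            "area": areas,
            "role": roles,
            "beds": beds,
            "in_prefecture": in_pref,
            "coop": coop,
            "x": px,
            "y": py,
        }
    )
    truth = GroundTruth(
        provider_coop=dict(zip(ids, coop.tolist())),
        provider_area=dict(zip(ids, areas.tolist())),
        provider_community=dict(zip(ids, areas.tolist())),
        community_offset=dict(enumerate(community_offset.tolist())),
    )
    return providers, truth


def generate_patients(config: SynthConfig, rng_seed: int | None = None) -> pd.DataFrame:
    """Patient table: id, home area, baseline age, sex.

    Ages are truncated-normal around 83 years and ~79% of patients are
    female, matching the elderly femoral-neck-fracture cohort regime.
    """
    config.validate()
    rng = np.random.default_rng(
        (config.seed if rng_seed is None else rng_seed) + 1_000_003
    )
    n = config.n_patients
    ages = np.clip(rng.normal(MEAN_AGE, 8.0, size=n), 55.0, 102.0)
    areas = rng.integers(0, config.n_areas, size=n)
    cx, cy = _area_centers(config.n_areas)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i:05d}" for i in range(n)],
            "area": areas,
            "age0": ages,
            "sex": np.where(rng.random(n) < 0.788, "female", "male"),
            "x": cx[areas] + rng.normal(0.0, config.geo_spread, size=n),
            "y": cy[areas] + rng.normal(0.0, config.geo_spread, size=n),
        }
    )


def _pick(rng: np.random.Generator, ids: np.ndarray, weights: np.ndarray,
          k: int = 1, exclude: set[str] | None = None) -> list[str]:
    if exclude:
        keep = np.array([i not in exclude for i in ids])
        ids, weights = ids[keep], weights[keep]
    if len(ids) == 0:
        return []
    k = min(k, len(ids))
    total = weights.sum()
    p = weights / total if total > 0 else np.full(len(ids), 1.0 / len(ids))
    return list(rng.choice(ids, size=k, replace=False, p=p))


def _provider_pools(providers: pd.DataFrame):
    """Per (role, area) and (role, -1=anywhere): ids, size-by-cooperation
    attractiveness, and coordinates."""
    pools: dict[tuple[str, int], tuple] = {}
    for role in ("acute", "recovery", "outpatient"):
        sub = providers[providers["role"] == role]
        keys: list[int] = [-1] + [int(a) for a in sorted(sub["area"].unique())]
        for key in keys:
            grp = sub if key == -1 else sub[sub["area"] == key]
            pools[(role, key)] = (
                grp["provider_id"].to_numpy(),
                (grp["beds"].to_numpy() + 1.0) * grp["coop"].to_numpy(),
                grp["x"].to_numpy(),
                grp["y"].to_numpy(),
            )
    return pools


def _geo_weights(pool, x: float, y: float, sigma: float) -> np.ndarray:
    ids, base, px, py = pool
    d2 = (px - x) ** 2 + (py - y) ** 2
    return base * np.exp(-d2 / (2.0 * sigma * sigma))


def generate_claims(
    providers: pd.DataFrame,
    patients: pd.DataFrame,
    config: SynthConfig,
    rng_seed: int | None = None,
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Generate the claims table for every patient fracture history.

    Per patient, fracture admissions recur with exponential gaps
    (mean ``mean_interfracture_days``) after the previous discharge.  Each
    fracture produces an acute inpatient stay (with surgery inside unless the
    patient is managed conservatively), a recovery-hospital stay with
    probability ``transfer_prob`` starting within a few days of the acute
    discharge, and outpatient visits on a ``outpatient_cycle_days`` lattice
    before admission and after discharge.  The realized stay length is::

        D = stay_base + age_effect * (age - 83.2) + coop_effect * g(x) + noise

    where ``x`` is the mean standardized log-cooperation of the hospitals
    used and ``g`` is the identity (linear regime) or a saturating
    ``tanh`` plus planted community offsets (nonlinear regime).  If
    ``ground_truth`` is passed, its ``case_effects`` table is filled in.
    """
    config.validate()
    if len(providers) == 0 or len(patients) == 0:
        raise ConfigError("providers and patients must be nonempty")
    rng = np.random.default_rng(
        (config.seed if rng_seed is None else rng_seed) + 2_000_029
    )
    start, end = config.horizon_dates
    horizon_days = (end - start).days

    log_coop = np.log(providers["coop"].to_numpy())
    mu_lc, sd_lc = log_coop.mean(), max(log_coop.std(), 1e-12)
    coop_z = dict(zip(providers["provider_id"], (log_coop - mu_lc) / sd_lc))
    in_pref = dict(zip(providers["provider_id"], providers["in_prefecture"]))
    comm = dict(zip(providers["provider_id"], providers["area"]))
    offsets = (ground_truth.community_offset if ground_truth is not None
               else {a: 0.0 for a in range(config.n_areas)})
    pools = _provider_pools(providers)
    cycle = config.outpatient_cycle_days

    rows: list[tuple] = []
    case_rows: list[dict] = []
    gaps_drawn: list[float] = []

    def add_inpatient(pid, mid, adm, dis, surg, age, sex):
        rows.append((pid, mid, "inpatient", adm.isoformat(), dis.isoformat(),
                     "", surg.isoformat() if surg else "", age, sex,
                     bool(in_pref[mid])))

    def add_outpatient(pid, mid, day, age, sex):
        rows.append((pid, mid, "outpatient", "", "", day.isoformat(), "",
                     age, sex, bool(in_pref[mid])))

    for pat in patients.itertuples(index=False):
        n_frac = rng.poisson(config.fracture_rate)
        if n_frac == 0:
            continue
        t = float(rng.uniform(0, horizon_days))
        prev_gap = np.nan
        for fx in range(n_frac):
            if t > horizon_days:
                break
            adm = start + timedelta(days=int(round(t)))
            age = int(pat.age0 + t / 365.25)
            area = int(pat.area)

            def pick_role(role, k=1, exclude=None):
                sigma = (config.sigma_clinic if role == "outpatient"
                         else config.sigma_hospital)
                if rng.random() < config.within_area_prob:
                    pool = pools[(role, area)]
                    w = _geo_weights(pool, pat.x, pat.y, sigma)
                else:  # long-range referral: attractiveness only
                    pool = pools[(role, -1)]
                    w = pool[1]
                return _pick(rng, pool[0], w, k=k, exclude=exclude)

            hospitals = pick_role("acute")
            n_transfers = 0
            if rng.random() < config.transfer_prob:
                n_transfers = 1
                if rng.random() < config.transfer_prob ** 2:
                    n_transfers = 2
            for _ in range(n_transfers):
                nxt = pick_role("recovery", exclude=set(hospitals))
                if nxt:
                    hospitals.extend(nxt)

            x = float(np.mean([coop_z[h] for h in hospitals]))
            if config.nonlinearity:
                off = float(offsets[int(comm[hospitals[0]])])
                effect = config.coop_effect * float(np.tanh(1.5 * x)) + off \
                    + 0.5 * off * x
            else:
                off = 0.0
                effect = config.coop_effect * x
            mean_stay = config.stay_base + config.age_effect * (age - MEAN_AGE) + effect
            noise = float(rng.normal(0.0, config.noise_sd))
            if rng.random() < config.heavy_tail_prob:
                noise += float(rng.lognormal(4.8, 0.9))  # rare long-stay tail
            D = int(max(3, round(mean_stay + noise)))

            has_surgery = rng.random() < config.surgery_prob
            # split D across the hospital chain, small within-tau1 gaps
            n_h = len(hospitals)
            if n_h == 1:
                bounds = [(0, D)]
            else:
                acute_days = max(3, min(D - 1, int(round(D * rng.uniform(0.25, 0.45)))))
                bounds = [(0, acute_days)]
                cur = acute_days
                remaining = list(range(1, n_h))
                for j, _h in enumerate(remaining):
                    gap = int(rng.integers(0, 5))
                    seg_end = D if j == len(remaining) - 1 else max(
                        cur + gap + 1, int(round(D * rng.uniform(0.6, 0.85))))
                    bounds.append((cur + gap, max(seg_end, cur + gap)))
                    cur = bounds[-1][1]
            last_dis = adm
            for h, (a_off, d_off) in zip(hospitals, bounds):
                a_day = adm + timedelta(days=a_off)
                d_day = adm + timedelta(days=max(d_off, a_off))
                surg = None
                if has_surgery and h == hospitals[0]:
                    surg = a_day + timedelta(days=int(rng.integers(0, min(4, d_off - a_off) + 1)))
                add_inpatient(pat.patient_id, h, a_day, d_day, surg, age, pat.sex)
                last_dis = max(last_dis, d_day)

            # outpatient partners: count scales with the admitting hospital's
            # cooperation, which is what ties latent cooperation to strength
            lam = config.partner_rate * float(np.exp(0.8 * coop_z[hospitals[0]]))
            n_clinics = 1 + int(rng.poisson(lam))
            clinics = pick_role("outpatient", k=n_clinics)
            n_pre = 1 + int(rng.geometric(0.45))
            n_post = 1 + int(rng.geometric(0.35))
            visits = [adm - timedelta(days=cycle * (k + 1)) for k in range(n_pre)]
            visits += [last_dis + timedelta(days=cycle * (k + 1)) for k in range(n_post)]
            last_care = max([last_dis] + visits)
            for k, day in enumerate(visits):
                if not (start <= day <= end):
                    continue
                if rng.random() < 0.2:  # occasional off-lattice visit
                    day = day + timedelta(days=int(rng.integers(-1, 2)))
                clinic = clinics[k % len(clinics)]
                add_outpatient(pat.patient_id, clinic, day, age, pat.sex)

            case_rows.append(
                {
                    "patient_id": pat.patient_id,
                    "fracture_index": fx,
                    "admission_date": adm.isoformat(),
                    "providers": ";".join(hospitals),
                    "coop_x": x,
                    "community_offset": off,
                    "expected_stay": mean_stay,
                    "realized_stay": D,
                    "has_surgery": has_surgery,
                    "interfracture_gap": prev_gap,
                }
            )
            # next fracture recurs after the post-fracture care window closes
            gap = float(rng.exponential(config.mean_interfracture_days))
            gaps_drawn.append(gap)
            prev_gap = gap
            t = (last_care - start).days + config.refracture_buffer_days + gap

    claims = pd.DataFrame(rows, columns=CLAIMS_COLUMNS)
    claims = claims.sort_values(
        ["patient_id", "admission_date", "visit_date", "record_type", "provider_id"],
        kind="stable",
    ).reset_index(drop=True)
    if ground_truth is not None:
        ground_truth.case_effects = pd.DataFrame(case_rows)
        ground_truth.interfracture_gaps = gaps_drawn
    return claims


def simulate(config: SynthConfig, rng_seed: int | None = None):
    """Run the full generator; returns (providers, patients, claims, truth)."""
    seed = config.seed if rng_seed is None else rng_seed
    providers, truth = generate_providers(config, seed)
    patients = generate_patients(config, seed)
    claims = generate_claims(providers, patients, config, seed, ground_truth=truth)
    return providers, patients, claims, truth


# ---------------------------------------------------------------------------
# claims CSV I/O


def records_to_claims(records: Iterable[ClaimRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            (
                r.patient_id,
                r.provider_id,
                r.record_type,
                r.admission_date.isoformat() if r.admission_date else "",
                r.discharge_date.isoformat() if r.discharge_date else "",
                r.visit_date.isoformat() if r.visit_date else "",
                r.surgery_date.isoformat() if r.surgery_date else "",
                int(r.age),
                r.sex,
                bool(r.in_prefecture),
            )
        )
    return pd.DataFrame(rows, columns=CLAIMS_COLUMNS)


def claims_to_records(claims: pd.DataFrame) -> list[ClaimRecord]:
    def d(v):
        return None if (v is None or v != v or v == "") else date.fromisoformat(str(v))

    out = []
    for row in claims.itertuples(index=False):
        out.append(
            ClaimRecord(
                patient_id=str(row.patient_id),
                provider_id=str(row.provider_id),
                record_type=str(row.record_type),
                admission_date=d(row.admission_date),
                discharge_date=d(row.discharge_date),
                visit_date=d(row.visit_date),
                surgery_date=d(row.surgery_date),
                age=int(row.age),
                sex=str(row.sex),
                in_prefecture=bool(row.in_prefecture),
            )
        )
    return out


class ClaimsSchemaError(ValueError):
    """Malformed claims file (bad columns or an invalid row)."""


def write_claims(records, path) -> None:
    """Write claims to CSV (ISO dates, UTF-8, header always present)."""
    if isinstance(records, pd.DataFrame):
        df = records[CLAIMS_COLUMNS].copy()
    else:
        df = records_to_claims(records)
    df.to_csv(path, index=False, lineterminator="\n")


def read_claims(path) -> pd.DataFrame:
    """Read and validate a claims CSV; raises with the offending line number."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != CLAIMS_COLUMNS:
        raise ClaimsSchemaError(
            f"bad header: expected {CLAIMS_COLUMNS}, got {list(df.columns)}"
        )
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rt = row.record_type
        if rt not in ("inpatient", "outpatient"):
            raise ClaimsSchemaError(f"line {line}: unknown record_type {rt!r}")
        try:
            if rt == "inpatient":
                adm = date.fromisoformat(row.admission_date)
                dis = date.fromisoformat(row.discharge_date)
                if row.visit_date:
                    raise ValueError("inpatient row has a visit_date")
                if dis < adm:
                    raise ValueError(f"discharge {dis} precedes admission {adm}")
                if row.surgery_date:
                    s = date.fromisoformat(row.surgery_date)
                    if not adm <= s <= dis:
                        raise ValueError("surgery date outside the stay")
            else:
                date.fromisoformat(row.visit_date)
                if row.admission_date or row.discharge_date or row.surgery_date:
                    raise ValueError("outpatient row has inpatient-only fields")
            int(row.age)
            if row.sex not in ("male", "female"):
                raise ValueError(f"bad sex {row.sex!r}")
            if row.in_prefecture not in ("True", "False"):
                raise ValueError(f"bad in_prefecture {row.in_prefecture!r}")
        except ValueError as exc:
            raise ClaimsSchemaError(f"line {line}: {exc}") from exc
    df = df.copy()
    df["age"] = df["age"].astype(int)
    df["in_prefecture"] = df["in_prefecture"] == "True"
    return df
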