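"""Synthetic administrative-claims cohorts with known true indications.

The generator emulates the five patient archetypes the exclusion algorithm
distinguishes, so the whole pipeline can be exercised — and its
misclassification behavior studied — without any external dataset:

HIV
    a prior HIV diagnosis (042 or V08) and concomitant other-antiretroviral
    fills alongside the TDF/FTC era;
CHB
    a prior chronic-hepatitis-B diagnosis, with hepatitis-B-agent fills for
    half of the patients;
PEP
    a single short era (one fill, mean 26 days of supply) with a
    needle-stick or prophylaxis code within a few days of the index date;
PREP
    a clean TDF/FTC era plus at least one diagnosis (high-risk sexual
    behavior, V69.2) and one procedure (prevention counseling, 99401-3);
MEDS_ONLY
    pharmacy rows only — no diagnoses or procedures anywhere, so the
    algorithm conservatively refuses to call the era PrEP.

Era durations are built from refill counts: a patient receives ``k`` refills
of ``refill_supply_days`` (default 30) days each, with ``k`` geometric with
mean ``target_mean / supply``, so the expected era duration equals the
configured per-indication mean (defaults 126 HIV / 239 CHB / 96 PrEP /
26 PEP days). Refills are contiguous by default; an optional within-era gap
distribution inserts supply gaps below the era-merge threshold. Truth is
recorded per era, not per patient, so longitudinal "PrEP then HIV" patients
can be composed from the parts.

Coding noise (:class:`NoiseConfig`) independently drops diagnosis and
procedure rows and injects miscodes at configured rates, leaving the truth
table untouched — the mechanism by which real claims misclassify in either
direction. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .claims_model import (
    ClinicalEvent,
    CohortDataset,
    GoldLabel,
    PharmacyClaim,
    write_cohort,
)
from .codebook import Codebook, CodeSystem

__all__ = [
    "NoiseConfig",
    "SimConfig",
    "TruthRecord",
    "SyntheticDataset",
    "SimulationError",
    "generate_cohort",
    "apply_noise",
]

INDICATIONS = ("HIV", "CHB", "PEP", "PREP", "MEDS_ONLY")

#: Per-indication mean TDF/FTC exposure durations (days).
DEFAULT_MEAN_DURATIONS = {"HIV": 126.0, "CHB": 239.0, "PREP": 96.0, "PEP": 26.0,
                          "MEDS_ONLY": 96.0}

_ARV_OTHER_GPI = "1210300010"
_HBV_AGENT_GPI = "1235200010"
_TDF_FTC_GPI = "1210990230"
_GENERIC_PX = ("99213", "80061", "36415")
_GENERIC_DX = "780.60"
_MISCODE_DX = "780.60"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseConfig:
    """Independent per-row / per-patient coding-noise rates, all in [0, 1]."""

    p_missing_dx: float = 0.0
    p_missing_px: float = 0.0
    p_miscode_hiv_dx: float = 0.0
    p_spurious_prophylaxis_code: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_missing_dx", "p_missing_px", "p_miscode_hiv_dx",
                     "p_spurious_prophylaxis_code"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")

    @property
    def any(self) -> bool:
        return any((self.p_missing_dx, self.p_missing_px,
                    self.p_miscode_hiv_dx, self.p_spurious_prophylaxis_code))


def _default_mixture() -> dict[str, float]:
    return {"HIV": 0.35, "CHB": 0.10, "PEP": 0.10, "PREP": 0.35, "MEDS_ONLY": 0.10}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort draw."""

    n_patients: int = 200
    mixture: dict[str, float] = field(default_factory=_default_mixture)
    mean_duration_days: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_DURATIONS))
    refill_supply_days: int = 30
    within_era_gap_max: int = 0  # uniform 0..max extra days between refills (< gap threshold)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    study_start: dt.date = dt.date(2012, 1, 1)
    study_end: dt.date = dt.date(2013, 12, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.mixture) - set(INDICATIONS)
        if unknown:
            raise SimulationError(f"unknown indications in mixture: {sorted(unknown)}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"mixture must sum to 1, got {total}")
        if any(p < 0 for p in self.mixture.values()):
            raise SimulationError("mixture proportions must be non-negative")
        for k, v in self.mean_duration_days.items():
            if v <= 0:
                raise SimulationError(f"mean duration for {k} must be > 0")
        if self.n_patients < 0:
            raise SimulationError("n_patients must be >= 0")
        if self.refill_supply_days < 1:
            raise SimulationError("refill_supply_days must be >= 1")
        if not 0 <= self.within_era_gap_max < 30:
            raise SimulationError("within_era_gap_max must be in [0, 30)")
        if self.study_end < self.study_start:
            raise SimulationError("study_end before study_start")


@dataclass(frozen=True)
class TruthRecord:
    patient_id: str
    era_start: dt.date
    true_indication: str


@dataclass
class SyntheticDataset:
    """A cohort plus the per-era ground truth used as the validation oracle."""

    dataset: CohortDataset
    truth: list[TruthRecord]

    def truth_label_map(self) -> dict[tuple[str, dt.date], str]:
        """Era-level gold labels: PREP iff the era's true indication is PrEP."""
        return {
            (t.patient_id, t.era_start): ("PREP" if t.true_indication == "PREP" else "NOT_PREP")
            for t in self.truth
        }

    def patient_truth_map(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for t in self.truth:
            if t.true_indication == "PREP":
                out[t.patient_id] = "PREP"
            else:
                out.setdefault(t.patient_id, "NOT_PREP")
        return out

    def with_gold(self, unit: str = "ERA") -> CohortDataset:
        """Return the cohort with truth attached as a gold-label table."""
        if unit == "ERA":
            gold = [GoldLabel(t.patient_id,
                              "PREP" if t.true_indication == "PREP" else "NOT_PREP",
                              t.era_start)
                    for t in self.truth]
        else:
            gold = [GoldLabel(pid, label)
                    for pid, label in sorted(self.patient_truth_map().items())]
        ds = self.dataset
        return CohortDataset(claims=ds.claims, events=ds.events, gold=gold,
                             rejections=ds.rejections)

    def write(self, out_dir: str | Path, unit: str = "ERA") -> dict[str, Path]:
        """Write pharmacy/dx/px/gold tables plus the truth CSV."""
        paths = write_cohort(self.with_gold(unit), out_dir)
        truth_path = Path(out_dir) / "truth.csv"
        pd.DataFrame(
            [(t.patient_id, t.era_start.isoformat(), t.true_indication)
             for t in sorted(self.truth, key=lambda t: (t.patient_id, t.era_start))],
            columns=["patient_id", "era_start", "true_indication"],
        ).to_csv(truth_path, index=False)
        paths["truth"] = truth_path
        return paths


class _IdFactory:
    def __init__(self) -> None:
        self._n = 0

    def __call__(self, prefix: str) -> str:
        self._n += 1
        return f"{prefix}{self._n:07d}"


def _era_fill_dates(rng: np.random.Generator, config: SimConfig,
                    indication: str, start: dt.date) -> list[tuple[dt.date, int]]:
    """(fill_date, days_supply) pairs for one era of the given indication."""
    if indication == "PEP":
        # Single short course; uniform 24..28 days of supply (mean 26).
        return [(start, int(rng.integers(24, 29)))]
    supply = config.refill_supply_days
    mean = config.mean_duration_days.get(indication, DEFAULT_MEAN_DURATIONS[indication])
    if mean <= supply:
        k = 1
    else:
        k = int(rng.geometric(supply / mean))
    fills = []
    date = start
    for i in range(k):
        fills.append((date, supply))
        gap = int(rng.integers(0, config.within_era_gap_max + 1)) if config.within_era_gap_max else 0
        date = date + dt.timedelta(days=supply + gap)
    return fills


def generate_cohort(config: SimConfig) -> SyntheticDataset:
    """Draw a synthetic cohort; same config (incl. seed) -> identical output.

    Each patient receives one TDF/FTC era whose true indication is drawn from
    the mixture, plus the indication's characteristic diagnosis, procedure
    and co-medication records. Configured noise is applied afterwards via
    :func:`apply_noise` (truth is never perturbed).
    """
    ss = np.random.SeedSequence(config.seed)
    gen_seed, noise_seed = ss.spawn(2)
    rng = np.random.default_rng(gen_seed)

    ids = _IdFactory()
    claims: list[PharmacyClaim] = []
    events: list[ClinicalEvent] = []
    truth: list[TruthRecord] = []

    names = list(INDICATIONS)
    probs = np.array([config.mixture.get(n, 0.0) for n in names], dtype=float)
    horizon = max(1, (config.study_end - config.study_start).days - 30)

    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        indication = names[int(rng.choice(len(names), p=probs))]
        start = config.study_start + dt.timedelta(days=int(rng.integers(0, horizon)))
        fills = _era_fill_dates(rng, config, indication, start)
        for date, supply in fills:
            claims.append(PharmacyClaim(pid, date, supply, _TDF_FTC_GPI, ids("C")))
        era_end = max(d + dt.timedelta(days=s - 1) for d, s in fills)

        def days_back(lo: int = 30, hi: int = 365) -> dt.timedelta:
            return dt.timedelta(days=int(rng.integers(lo, hi)))

        if indication != "MEDS_ONLY":
            # patients in care carry nonspecific diagnoses besides their
            # indication markers (encounter evidence survives a dropped marker)
            events.append(ClinicalEvent(pid, start, CodeSystem.ICD9_DX, _GENERIC_DX))

        if indication == "HIV":
            code = "042" if rng.random() < 0.7 else "V08"
            events.append(ClinicalEvent(pid, start - days_back(), CodeSystem.ICD9_DX, code))
            for date, supply in fills:
                claims.append(PharmacyClaim(pid, date, supply, _ARV_OTHER_GPI, ids("C")))
            events.append(ClinicalEvent(pid, start, CodeSystem.CPT,
                                        str(rng.choice(_GENERIC_PX))))
        elif indication == "CHB":
            code = str(rng.choice(["070.22", "070.23", "070.32", "070.33"]))
            events.append(ClinicalEvent(pid, start - days_back(), CodeSystem.ICD9_DX, code))
            if rng.random() < 0.5:
                for date, supply in fills:
                    claims.append(PharmacyClaim(pid, date, supply, _HBV_AGENT_GPI, ids("C")))
            events.append(ClinicalEvent(pid, start, CodeSystem.CPT,
                                        str(rng.choice(_GENERIC_PX))))
        elif indication == "PEP":
            code = "E920.5" if rng.random() < 0.5 else "V07.8"
            offset = dt.timedelta(days=int(rng.integers(-3, 4)))
            events.append(ClinicalEvent(pid, start + offset, CodeSystem.ICD9_DX, code))
            events.append(ClinicalEvent(pid, start, CodeSystem.CPT,
                                        str(rng.choice(_GENERIC_PX))))
        elif indication == "PREP":
            span = max(1, (era_end - start).days)
            dx_date = start + dt.timedelta(days=int(rng.integers(0, span)))
            events.append(ClinicalEvent(pid, dx_date, CodeSystem.ICD9_DX, "V69.2"))
            px_date = start + dt.timedelta(days=int(rng.integers(0, span)))
            events.append(ClinicalEvent(pid, px_date, CodeSystem.CPT,
                                        str(rng.choice(["99401", "99402", "99403"]))))
        # MEDS_ONLY: pharmacy rows only.

        truth.append(TruthRecord(pid, start, indication))

    sds = SyntheticDataset(
        dataset=CohortDataset(claims=claims, events=events).sorted(),
        truth=sorted(truth, key=lambda t: (t.patient_id, t.era_start)),
    )
    if config.noise.any:
        sds = apply_noise(sds, config.noise,
                          seed=int(noise_seed.generate_state(1)[0] % (2**31)))
    return sds


def apply_noise(
    sds: SyntheticDataset,
    noise: NoiseConfig,
    seed: int = 0,
    book: Codebook | None = None,
) -> SyntheticDataset:
    """Perturb a synthetic dataset's coded records; truth is untouched.

    Diagnosis and procedure rows are dropped independently at the configured
    rates; HIV diagnosis codes are miscoded to an unrelated symptom code at
    ``p_miscode_hiv_dx``; spurious prophylaxis codes are injected per patient
    at ``p_spurious_prophylaxis_code``. Drop decisions use one uniform draw
    per row in canonical row order, so for a fixed seed the dropped sets are
    nested as the rates grow — increasing a rate only ever removes more rows.
    """
    book = book or Codebook()
    rng = np.random.default_rng(seed)
    ds = sds.dataset.sorted()

    kept_events: list[ClinicalEvent] = []
    for ev in ds.events:
        p_drop = noise.p_missing_dx if ev.system is CodeSystem.ICD9_DX else noise.p_missing_px
        if rng.random() < p_drop:
            continue
        kept_events.append(ev)

    if noise.p_miscode_hiv_dx > 0:
        miscoded = []
        for ev in kept_events:
            if (ev.system is CodeSystem.ICD9_DX
                    and "HIV_DX" in book.categorize_event(ev.system, ev.code)
                    and rng.random() < noise.p_miscode_hiv_dx):
                ev = replace(ev, code=_MISCODE_DX)
            miscoded.append(ev)
        kept_events = miscoded

    if noise.p_spurious_prophylaxis_code > 0:
        first_claim: dict[str, dt.date] = {}
        for c in ds.claims:
            if c.patient_id not in first_claim or c.fill_date < first_claim[c.patient_id]:
                first_claim[c.patient_id] = c.fill_date
        for pid in sorted(first_claim):
            if rng.random() < noise.p_spurious_prophylaxis_code:
                kept_events.append(
                    ClinicalEvent(pid, first_claim[pid], CodeSystem.ICD9_DX, "V07.8"))

    noisy = CohortDataset(claims=list(ds.claims), events=kept_events,
                          gold=ds.gold, rejections=list(ds.rejections)).sorted()
    return SyntheticDataset(dataset=noisy, truth=list(sds.truth))
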