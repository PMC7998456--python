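"""Synthetic clinical-study generators.

No individual-level data are published for the studies this package
emulates, so every pipeline stage is exercised on synthetic datasets drawn
from the published population model:

* the internal crossover study: 16 healthy subjects, single IV infusions of
  5/10/20 mg on three occasions separated by washout, 24-h plasma and pH
  sampling;
* the external single-dose study: 10 subjects at 30 mg, 24-h sampling;
* the loading-dose studies: 12 healthy subjects or 10 duodenal-ulcer
  patients on 20 mg (day 1) then 10 mg daily (days 2-3), monitored 72 h.

Each generator returns a :class:`~ppipkpd.dataset.StudyDataset` whose
manifest records the design, the seeds, the generating parameters and the
per-subject simulation truth (weights, etas, individual PK values).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import model_core as mc
from .dataset import StudyDataset
from .params import (
    Demographics,
    HEALTHY_STUDY_DEMOGRAPHICS,
    ILAPRAZOLE_PD,
    ILAPRAZOLE_PK,
    PDParameters,
    PKParameters,
)
from .trial_simulation import (
    DEFAULT_CONC_TIMES,
    DEFAULT_PH_INTERVAL,
    sample_population,
    simulate_trial,
)

__all__ = [
    "StudyDesign",
    "generate_internal_study",
    "generate_external_30mg",
    "generate_loading_dose_study",
]


@dataclass(frozen=True)
class StudyDesign:
    """Label, arms and observation schedules of one emulated study."""

    label: str
    arms: tuple[dict, ...]
    conc_times: tuple[float, ...]
    ph_times: tuple[float, ...]
    horizon: float

    def __post_init__(self):
        if not self.arms:
            raise ValueError("study must have at least one arm")
        for times in (self.conc_times, self.ph_times):
            if times and (min(times) < 0 or max(times) > self.horizon):
                raise ValueError("observation schedules must lie within the horizon")


def _manifest(study, seed, pk, pd_params, subjects, arms):
    om = np.array(pk.omegas())
    om_pd = np.array(pd_params.omegas())
    subs = []
    for s in subjects:
        eta_pk = om * s.eta_pk
        ind = mc.individual_parameters(pk, s.weight, s.sex, eta_pk)
        subs.append({
            "id": s.id,
            "weight": s.weight,
            "sex": s.sex,
            "eta_pk": list(eta_pk),
            "eta_pd": list(om_pd * s.eta_pd),
            "pk_individual": {"CLp": ind.CLp, "CLt": ind.CLt, "Vc": ind.Vc, "Vt": ind.Vt},
        })
    return {
        "study": study,
        "seed": seed,
        "n_subjects": len(subjects),
        "arms": arms,
        "parameters": {"pk": asdict(pk), "pd": asdict(pd_params)},
        "subjects": subs,
    }


def _ph_grid(horizon: float, interval: float) -> np.ndarray:
    return np.round(np.arange(0.0, horizon + interval / 2, interval), 9)


def generate_internal_study(pk: PKParameters = ILAPRAZOLE_PK,
                            pd_params: PDParameters = ILAPRAZOLE_PD,
                            seed: int = 0, *, n_subjects: int = 16,
                            doses=(5.0, 10.0, 20.0),
                            conc_times=DEFAULT_CONC_TIMES,
                            ph_interval: float = DEFAULT_PH_INTERVAL,
                            demographics: Demographics = HEALTHY_STUDY_DEMOGRAPHICS,
                            with_noise: bool = True) -> StudyDataset:
    """Crossover single-dose study: each subject receives every IV dose on a
    separate occasion (1-week washout -> occasions are independent 24-h days
    sharing the subject's random effects; no inter-occasion variability)."""
    ss = np.random.default_rng(seed).integers(0, 2**31 - 1, size=1 + len(doses))
    subjects = sample_population(n_subjects, demographics, int(ss[0]))
    ph_times = _ph_grid(24.0, ph_interval)
    frames = []
    arms = []
    for occ, dose in enumerate(doses, start=1):
        reg = mc.daily_regimen([dose], f"{dose:g} mg IV", horizon=24.0)
        ds = simulate_trial(subjects, reg, pk, pd_params, conc_times, ph_times,
                            seed=int(ss[occ]), with_noise=with_noise, occ=occ)
        frames.append(ds.records)
        arms.append({"occasion": occ, "dose_mg": dose, "n": n_subjects, "horizon_h": 24.0})
    import pandas as pd

    records = pd.concat(frames, ignore_index=True)
    manifest = _manifest("internal", seed, pk, pd_params, subjects, arms)
    manifest["conc_times"] = list(conc_times)
    manifest["ph_interval_h"] = ph_interval
    return StudyDataset(records, manifest)


def generate_external_30mg(pk: PKParameters = ILAPRAZOLE_PK,
                           pd_params: PDParameters = ILAPRAZOLE_PD,
                           seed: int = 0, *, n_subjects: int = 10,
                           dose: float = 30.0,
                           conc_times=DEFAULT_CONC_TIMES,
                           ph_interval: float = DEFAULT_PH_INTERVAL,
                           demographics: Demographics = HEALTHY_STUDY_DEMOGRAPHICS,
                           with_noise: bool = True) -> StudyDataset:
    """External validation arm: one 30 mg infusion, 24-h monitoring."""
    ss = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2)
    subjects = sample_population(n_subjects, demographics, int(ss[0]))
    reg = mc.daily_regimen([dose], f"{dose:g} mg IV", horizon=24.0)
    ds = simulate_trial(subjects, reg, pk, pd_params, conc_times,
                        _ph_grid(24.0, ph_interval), seed=int(ss[1]),
                        with_noise=with_noise)
    arms = [{"occasion": 1, "dose_mg": dose, "n": n_subjects, "horizon_h": 24.0}]
    manifest = _manifest("external_30mg", seed, pk, pd_params, subjects, arms)
    return StudyDataset(ds.records, manifest)


def generate_loading_dose_study(pk: PKParameters = ILAPRAZOLE_PK,
                                pd_params: PDParameters = ILAPRAZOLE_PD,
                                seed: int = 0, *, population: str = "healthy",
                                conc_offsets=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0),
                                ph_interval: float = DEFAULT_PH_INTERVAL,
                                demographics: Demographics = HEALTHY_STUDY_DEMOGRAPHICS,
                                with_noise: bool = True) -> StudyDataset:
    """Loading-dose study: 20 mg at 08:00 day 1 then 10 mg daily, 72-h
    monitoring.  ``population`` selects the arm size (12 healthy, 10
    duodenal-ulcer); both use the same parameters, reflecting the reported
    similarity of PK and acid inhibition between the groups."""
    if population not in ("healthy", "ulcer"):
        raise ValueError("population must be 'healthy' or 'ulcer'")
    n_subjects = 12 if population == "healthy" else 10
    ss = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2)
    subjects = sample_population(n_subjects, demographics, int(ss[0]))
    reg = mc.daily_regimen([20.0, 10.0, 10.0], "20/10/10 mg IV", horizon=72.0)
    conc_times = np.round(np.unique(
        [24.0 * day + off for day in range(3) for off in conc_offsets] + [24.0, 48.0, 72.0]
    ), 9)
    ds = simulate_trial(subjects, reg, pk, pd_params, conc_times,
                        _ph_grid(72.0, ph_interval), seed=int(ss[1]),
                        with_noise=with_noise)
    arms = [{"occasion": 1, "doses_mg": [20.0, 10.0, 10.0], "n": n_subjects,
             "horizon_h": 72.0, "population": population}]
    manifest = _manifest(f"loading_{population}", seed, pk, pd_params, subjects, arms)
    return StudyDataset(ds.records, manifest)
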