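"""Synthetic studies emulating the ECMO voriconazole trial design.

The generator reproduces the study's observable structure so every
downstream stage (estimation, simulation, diagnostics) can be exercised
without access to the raw clinical concentrations:

* 31 subjects by default, weights from a truncated normal (mean 87 kg,
  bounds 49-134 kg), CYP2C19 metabolizer mix 12 NM / 12 IM / 5 RM /
  1 PM / 1 UM;
* standard-of-care dosing (6 mg/kg q12h x2 loading then 4 mg/kg q12h,
  2 h infusions);
* sparse protocol sampling: in days 1-5 a near-peak sample 1-3 h after
  the end of an infusion, an elimination sample 5-7 h post-infusion and a
  pre-dose trough, all anchored to one dosing interval; single troughs in
  days 6-10 and 11-14;
* dropout (ECMO decannulation / drug discontinuation) drawn from the
  cohort's ECMO-duration strata, truncating both dosing and sampling;
* combined residual error and an assay LLOQ of 0.01 mg/L (values below
  the LLOQ are flagged, never deleted).

True individual parameters and noise-free concentrations are retained in
a truth table for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import DoseEvent, InfusionSystem
from .population import (PatientCovariates, PopulationParams,
                         IndividualEffects, individual_params,
                         sample_effects_array, sample_genotypes,
                         apply_residual_error, _rng)
from .regimen import RegimenSpec, build_regimen, get_preset

__all__ = ["StudyDesign", "StudyDataset", "simulate_study", "dropout_times",
           "simulate_rich_study", "rich_sampling_times", "RECORD_COLUMNS"]

RECORD_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV", "BLQ",
                  "WT", "GENO"]

#: ECMO-duration strata: (low days, high days, probability).  The last,
#: open-ended stratum means the subject completes every sampling window.
DEFAULT_DROPOUT_STRATA = (
    (0.5, 5.0, 10 / 31),
    (5.0, 10.0, 8 / 31),
    (10.0, 14.0, 4 / 31),
    (14.0, None, 9 / 31),
)


@dataclass(frozen=True)
class StudyDesign:
    n_subjects: int = 31
    weight_mean: float = 87.0
    weight_sd: float = 20.0
    weight_bounds: tuple[float, float] = (49.0, 134.0)
    genotype_frequencies: dict | None = None
    exact_genotypes: bool = False
    dropout_strata: tuple = DEFAULT_DROPOUT_STRATA
    horizon: float = 336.0          # h; 14 days of therapy
    early_window: tuple[float, float] = (0.0, 120.0)       # days 1-5, h
    mid_window: tuple[float, float] = (120.0, 240.0)       # days 6-10, h
    late_window: tuple[float, float] = (240.0, 336.0)      # days 11-14, h
    peak_offset: tuple[float, float] = (1.0, 3.0)          # h post-infusion
    elim_offset: tuple[float, float] = (5.0, 7.0)          # h post-infusion
    trough_lead: tuple[float, float] = (0.1, 0.5)          # h before next dose
    extra_trough_rate: float = 0.0  # Poisson mean of opportunistic TDM troughs
    lloq: float = 0.01              # mg/L

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.lloq < 0:
            raise ValueError("LLOQ must be >= 0")
        probs = [s[2] for s in self.dropout_strata]
        if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
            raise ValueError("dropout strata probabilities must sum to 1")


@dataclass
class StudyDataset:
    """Long-format dosing/observation records plus an optional truth table.

    ``records`` uses NONMEM-style columns (ID, TIME, AMT, RATE, EVID, DV,
    MDV, BLQ, WT, GENO); observation rows generated synthetically also
    carry the noise-free concentration in ``TRUEDV``.  ``truth`` holds one
    row per subject with the individual parameters and random effects that
    generated the data.
    """

    records: pd.DataFrame
    truth: pd.DataFrame | None = None
    design: StudyDesign | None = None
    population: PopulationParams | None = None

    @property
    def subject_ids(self) -> np.ndarray:
        return self.records["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.size

    def observations(self) -> pd.DataFrame:
        rec = self.records
        return rec[(rec["EVID"] == 0) & (rec["MDV"] == 0)]

    def doses(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 1]

    def subject(self, subject_id) -> "SubjectRecords":
        rec = self.records[self.records["ID"] == subject_id]
        if rec.empty:
            raise KeyError(f"no such subject: {subject_id}")
        return SubjectRecords.from_frame(rec)

    def subjects(self) -> list["SubjectRecords"]:
        return [self.subject(i) for i in self.subject_ids]


@dataclass
class SubjectRecords:
    """One subject's design: dose events, observation times and covariates."""

    subject_id: int
    doses: list[DoseEvent]
    obs_times: np.ndarray
    dv: np.ndarray
    covariates: PatientCovariates
    system: InfusionSystem = field(init=False, repr=False)

    def __post_init__(self) -> None:
        # order 10 suffices on infusion-length segments (validated against
        # stiff ODE integration to ~1e-9) and halves the estimation cost
        self.system = InfusionSystem(self.obs_times, self.doses, n_quad=10)

    @classmethod
    def from_frame(cls, rec: pd.DataFrame) -> "SubjectRecords":
        dose_rows = rec[rec["EVID"] == 1]
        obs_rows = rec[(rec["EVID"] == 0) & (rec["MDV"] == 0)].sort_values("TIME")
        doses = [DoseEvent(start_time=float(r.TIME), amount=float(r.AMT),
                           duration=float(r.AMT) / float(r.RATE))
                 for r in dose_rows.itertuples()]
        weight = float(rec["WT"].iloc[0]) if "WT" in rec else 70.0
        geno = str(rec["GENO"].iloc[0]) if "GENO" in rec else "NM"
        return cls(subject_id=int(rec["ID"].iloc[0]), doses=doses,
                   obs_times=obs_rows["TIME"].to_numpy(dtype=float),
                   dv=obs_rows["DV"].to_numpy(dtype=float),
                   covariates=PatientCovariates(weight=weight,
                                                genotype_class=geno))


def dropout_times(design: StudyDesign, n: int, seed=None) -> np.ndarray:
    """Sampling/dosing stop times (h) from the ECMO-duration strata.

    Subjects in the open-ended stratum run the full study (np.inf).
    Placement within a bounded stratum is uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    probs = np.array([s[2] for s in design.dropout_strata])
    idx = rng.choice(len(design.dropout_strata), size=n, p=probs)
    out = np.empty(n)
    for i, stratum in enumerate(idx):
        lo, hi, _ = design.dropout_strata[stratum]
        if hi is None:
            out[i] = np.inf
        else:
            out[i] = rng.uniform(lo * 24.0, hi * 24.0)
    return out


def _protocol_times(design: StudyDesign, doses: list[DoseEvent],
                    interval: float, stop: float, rng) -> np.ndarray:
    """Draw protocol sampling times for one subject, truncated at ``stop``."""
    times: list[float] = []
    starts = np.array([d.start_time for d in doses])
    ends = np.array([d.end_time for d in doses])

    # early window: three samples anchored to one complete dosing interval
    lo, hi = design.early_window
    ok = (starts >= lo) & (starts < hi) & (starts + interval <= min(stop, hi + interval))
    if ok.any():
        a = rng.choice(np.flatnonzero(ok))
        peak = ends[a] + rng.uniform(*design.peak_offset)
        elim = ends[a] + rng.uniform(*design.elim_offset)
        trough = starts[a] + interval - rng.uniform(*design.trough_lead)
        times += [t for t in (peak, elim, trough) if t <= stop]
    elif starts.size:
        peak = ends[0] + rng.uniform(*design.peak_offset)
        if peak <= stop:
            times.append(peak)

    # single troughs in the intermediate and late windows
    for lo, hi in (design.mid_window, design.late_window):
        t_trough = starts + interval
        ok = (t_trough > lo) & (t_trough <= hi) & (t_trough <= stop)
        if ok.any():
            a = rng.choice(np.flatnonzero(ok))
            times.append(starts[a] + interval - rng.uniform(*design.trough_lead))

    # opportunistic TDM troughs
    if design.extra_trough_rate > 0:
        n_extra = rng.poisson(design.extra_trough_rate)
        t_trough = starts + interval
        ok = t_trough <= min(stop, design.horizon)
        pool = np.flatnonzero(ok)
        for _ in range(min(n_extra, pool.size)):
            a = rng.choice(pool)
            times.append(starts[a] + interval - rng.uniform(*design.trough_lead))

    return np.unique(np.asarray(times, dtype=float))


def simulate_study(design: StudyDesign, pop: PopulationParams,
                   regimen: RegimenSpec | str = "smpc",
                   seed=None) -> StudyDataset:
    """Simulate a full study: covariates, dosing, sampling, noise, dropout."""
    rng = _rng(seed)
    if isinstance(regimen, str):
        regimen = get_preset(regimen)

    lo, hi = design.weight_bounds
    if design.weight_sd > 0:
        a = (lo - design.weight_mean) / design.weight_sd
        b = (hi - design.weight_mean) / design.weight_sd
        weights = stats.truncnorm.rvs(a, b, loc=design.weight_mean,
                                      scale=design.weight_sd,
                                      size=design.n_subjects,
                                      random_state=rng)
    else:
        weights = np.full(design.n_subjects, design.weight_mean)
    genotypes = sample_genotypes(design.n_subjects, seed=rng,
                                 frequencies=design.genotype_frequencies,
                                 exact_counts=design.exact_genotypes)
    etas = sample_effects_array(pop, design.n_subjects, seed=rng)
    stops = dropout_times(design, design.n_subjects, seed=rng)

    records = []
    truth_rows = []
    for i in range(design.n_subjects):
        sid = i + 1
        cov = PatientCovariates(weight=float(weights[i]),
                                genotype_class=genotypes[i])
        eta = IndividualEffects.from_array(etas[i])
        params = individual_params(pop, cov, eta)
        stop = float(min(stops[i], design.horizon))
        doses = build_regimen(regimen, cov.weight, horizon=stop)
        if not doses:  # stop before the first interval still gets the LD
            doses = build_regimen(regimen, cov.weight,
                                  horizon=regimen.interval)

        obs_times = _protocol_times(design, doses, regimen.interval, stop, rng)
        if obs_times.size == 0:  # guarantee at least one observation
            obs_times = np.array([min(stop, doses[0].end_time + 1.0)])

        system = InfusionSystem(obs_times, doses)
        true_conc = system.solve_params(params)
        dv, _ = apply_residual_error(true_conc, pop, seed=rng)

        for d in doses:
            records.append((sid, d.start_time, d.amount, d.rate, 1,
                            np.nan, 1, 0, cov.weight, cov.genotype_class,
                            np.nan))
        for t, y, f in zip(obs_times, dv, true_conc):
            records.append((sid, t, 0.0, 0.0, 0, y, 0,
                            int(y < design.lloq), cov.weight,
                            cov.genotype_class, f))

        truth_rows.append({
            "ID": sid, "WT": cov.weight, "GENO": cov.genotype_class,
            "stop_time": stop,
            "eta_V": eta.eta_V, "eta_CL1": eta.eta_CL1,
            "eta_CL2": eta.eta_CL2, "eta_Tswitch": eta.eta_Tswitch,
            "V": params.V, "CL1": params.CL1, "CL2": params.CL2,
            "Tswitch": params.Tswitch, "k": params.k,
            "CLseq0": params.CLseq0, "Thalf_seq": params.Thalf_seq,
        })

    rec = pd.DataFrame(records, columns=RECORD_COLUMNS + ["TRUEDV"])
    rec = rec.sort_values(["ID", "TIME", "EVID"], kind="stable",
                          ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return StudyDataset(records=rec, truth=truth, design=design,
                        population=pop)


def rich_sampling_times(interval: float = 12.0,
                        anchor_starts=(0.0, 48.0, 144.0, 312.0),
                        infusion_duration: float = 2.0) -> np.ndarray:
    """Twelve sampling times spanning days 1-14: near-peak (1 h after the end
    of the infusion), mid-interval and pre-dose trough in four dosing
    intervals covering the early, transitional and late phases."""
    out = []
    for s in anchor_starts:
        out += [s + infusion_duration + 1.0, s + 7.0, s + interval - 0.1]
    return np.asarray(sorted(out))


def simulate_rich_study(pop: PopulationParams, n_subjects: int = 50,
                        regimen: RegimenSpec | str = "smpc", seed=None,
                        sample_times=None, genotype: str | None = "NM",
                        design: StudyDesign | None = None) -> StudyDataset:
    """A rich-sampling, no-dropout study for parameter-recovery work.

    Every subject is sampled at the same fixed times (default:
    :func:`rich_sampling_times`, 12 samples over 14 days of therapy).
    ``genotype`` pins all subjects to one metabolizer class (default NM,
    making the genotype effect inert); pass ``None`` to sample the cohort
    mix instead.
    """
    rng = _rng(seed)
    if isinstance(regimen, str):
        regimen = get_preset(regimen)
    design = design if design is not None else StudyDesign(n_subjects=n_subjects)
    if sample_times is None:
        sample_times = rich_sampling_times(
            interval=regimen.interval,
            infusion_duration=regimen.infusion_duration)
    sample_times = np.asarray(sample_times, dtype=float)
    horizon = max(design.horizon, sample_times.max())

    lo, hi = design.weight_bounds
    a = (lo - design.weight_mean) / design.weight_sd
    b = (hi - design.weight_mean) / design.weight_sd
    weights = stats.truncnorm.rvs(a, b, loc=design.weight_mean,
                                  scale=design.weight_sd, size=n_subjects,
                                  random_state=rng)
    if genotype is None:
        genotypes = sample_genotypes(n_subjects, seed=rng,
                                     frequencies=design.genotype_frequencies)
    else:
        genotypes = [genotype] * n_subjects
    etas = sample_effects_array(pop, n_subjects, seed=rng)

    records, truth_rows = [], []
    for i in range(n_subjects):
        sid = i + 1
        cov = PatientCovariates(weight=float(weights[i]),
                                genotype_class=genotypes[i])
        eta = IndividualEffects.from_array(etas[i])
        params = individual_params(pop, cov, eta)
        doses = build_regimen(regimen, cov.weight, horizon=horizon)
        system = InfusionSystem(sample_times, doses)
        true_conc = system.solve_params(params)
        dv, _ = apply_residual_error(true_conc, pop, seed=rng)
        for d in doses:
            records.append((sid, d.start_time, d.amount, d.rate, 1,
                            np.nan, 1, 0, cov.weight, cov.genotype_class,
                            np.nan))
        for t, y, f in zip(sample_times, dv, true_conc):
            records.append((sid, t, 0.0, 0.0, 0, y, 0,
                            int(y < design.lloq), cov.weight,
                            cov.genotype_class, f))
        truth_rows.append({
            "ID": sid, "WT": cov.weight, "GENO": cov.genotype_class,
            "stop_time": horizon,
            "eta_V": eta.eta_V, "eta_CL1": eta.eta_CL1,
            "eta_CL2": eta.eta_CL2, "eta_Tswitch": eta.eta_Tswitch,
            "V": params.V, "CL1": params.CL1, "CL2": params.CL2,
            "Tswitch": params.Tswitch, "k": params.k,
            "CLseq0": params.CLseq0, "Thalf_seq": params.Thalf_seq,
        })

    rec = pd.DataFrame(records, columns=RECORD_COLUMNS + ["TRUEDV"])
    rec = rec.sort_values(["ID", "TIME", "EVID"], kind="stable",
                          ignore_index=True)
    return StudyDataset(records=rec, truth=pd.DataFrame(truth_rows),
                        design=design, population=pop)
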