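"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators cover the three pipeline stages:

* behavioral cohorts — seeded race-model sessions for two groups whose GO
  and STOP latency distributions differ by the between-group shifts seen
  in the study populations (healthy-control-like GO ~ N(269, 50) ms with
  STOP ~ N(99, 20) ms versus relative-like GO ~ N(317, 35) ms with STOP ~
  N(136, 25) ms, a 37 ms stop-latency gap);
* gaze traces — position time series built to round-trip through the
  online positional classifier (compensated / noncompensated / unchanged);
* group BOLD — subject-level bilinear-network parameters split around a
  base set by chosen connection effects, pushed through the balloon
  forward model at a requested SNR, with the ground truth returned for
  recovery tests.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError, StabilityError
from .race_model import RaceParameters, TaskConfig, SessionResult, simulate_session
from .inhibition_metrics import GazeTrial
from . import dcm_network as dcm

#: Default group race parameters (ms), calibrated to the two-group
#: behavioral summary of the stop-signal study populations.
HC_LIKE = RaceParameters(go_mean=269.0, go_sd=50.0, stop_mean=99.0, stop_sd=20.0)
REL_LIKE = RaceParameters(go_mean=317.0, go_sd=35.0, stop_mean=136.0, stop_sd=25.0)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group behavioral cohort specification."""

    n_per_group: tuple[int, int] = (14, 12)
    labels: tuple[str, str] = ("HC", "REL")
    params: tuple[RaceParameters, RaceParameters] = (HC_LIKE, REL_LIKE)
    task: TaskConfig = field(default_factory=TaskConfig.stop_signal)
    seed_base: int = 0
    jitter_rt_sd: float = 10.0  # between-subject sd added to both latency means (ms)

    def __post_init__(self):
        if min(self.n_per_group) < 2:
            raise InvalidInputError("need n_per_group >= 2 in both groups")


def generate_cohort_behavior(spec: CohortSpec) -> list[tuple[str, str, SessionResult]]:
    """One seeded session per subject: (subject_id, group, session) triples.

    Subject latency means get Gaussian between-subject jitter
    (sd ``jitter_rt_sd``); each subject's session seed derives
    deterministically from ``seed_base``.
    """
    rng = np.random.default_rng(spec.seed_base)
    out = []
    for g, (label, base, n) in enumerate(zip(spec.labels, spec.params, spec.n_per_group)):
        for i in range(n):
            subj_seed = int(rng.integers(0, 2**31 - 1))
            jit = rng.normal(0.0, spec.jitter_rt_sd, size=2)
            params = replace(
                base,
                go_mean=max(base.go_mean + jit[0], 1.0),
                stop_mean=max(base.stop_mean + jit[1], 1.0),
            )
            out.append((f"{label}{i:02d}", label, simulate_session(params, spec.task, subj_seed)))
    return out


@dataclass(frozen=True)
class GazeGeometry:
    """Target geometry for a redirect trial (directions in degrees,
    eccentricity in degrees of visual angle)."""

    t1_direction: float = 0.0
    t2_direction: float = 180.0
    target_eccentricity: float = 9.0
    array_onset: float = 1000.0

    def __post_init__(self):
        d = abs((self.t1_direction - self.t2_direction) % 360.0)
        if min(d, 360.0 - d) < 90.0:
            raise InvalidInputError("T1 and T2 must be at least 90 degrees apart")


def generate_gaze_trace(
    label: str,
    geometry: GazeGeometry = GazeGeometry(),
    sampling_interval: float = 1000.0 / 60.0,
    noise_deg: float = 0.2,
    seed: int = 0,
    saccade_time: float = 180.0,
    trial_duration: float = 800.0,
) -> GazeTrial:
    """A gaze trace that the positional classifier maps back to ``label``.

    The eye holds fixation, then (for compensated/noncompensated labels)
    steps to the target eccentricity along T2 or T1 respectively,
    ``saccade_time`` ms after array onset; for ``unchanged`` it never
    leaves fixation.  Gaussian position noise of ``noise_deg`` is added
    throughout.
    """
    if label not in ("compensated", "noncompensated", "unchanged"):
        raise InvalidInputError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(-200.0, trial_duration, sampling_interval) + geometry.array_onset
    xy = np.zeros((t.size, 2))
    if label != "unchanged":
        direction = geometry.t2_direction if label == "compensated" else geometry.t1_direction
        rad = np.radians(direction)
        target = geometry.target_eccentricity * np.array([np.cos(rad), np.sin(rad)])
        move_t = geometry.array_onset + saccade_time
        ramp = np.clip((t - move_t) / 30.0, 0.0, 1.0)  # ~30 ms saccade
        xy = ramp[:, None] * target[None, :]
    xy = xy + rng.normal(0.0, noise_deg, size=xy.shape)
    return GazeTrial(
        samples=np.column_stack([t, xy]),
        array_onset=geometry.array_onset,
        t1_direction=geometry.t1_direction,
        t2_direction=geometry.t2_direction,
        sampling_interval=sampling_interval,
    )


# ---------------------------------------------------------------------------
# network cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupEffectSpec:
    """A group difference planted on one connection.

    ``edge`` is a (source, target) pair or a region name for a
    self-connection; ``matrix`` selects average connectivity ('A') or
    redirect modulation ('B'); ``effect`` is the full between-group
    difference (Hz for edges, log-units for selves): group +1 gets
    +effect/2, group -1 gets -effect/2.
    """

    edge: tuple[str, str] | str
    effect: float
    matrix: str = "A"

    def __post_init__(self):
        if self.matrix not in ("A", "B"):
            raise InvalidInputError("matrix must be 'A' or 'B'")


def default_dcm_parameters(structure: Optional[dcm.NetworkStructure] = None) -> dcm.DCMParameters:
    """A fixed, stable base parameter set used as the cohort template.

    Edge weights alternate sign with magnitudes cycling through
    0.27/0.36/0.45 Hz in the canonical edge order, self log-scales spread
    over +/-0.25 around the -0.5 Hz default, redirect modulation is
    +0.2 Hz on the first four edges, and the driving-input gains differ
    across regions (0.32-0.80).  Heterogeneous gains and couplings of
    this size keep the region signals linearly well separated, which is
    what makes the connectivity identifiable from BOLD at realistic scan
    lengths; the set is comfortably stable (largest Jacobian eigenvalue
    real part about -0.12).
    """
    st = structure or dcm.build_structure()
    p = dcm.DCMParameters.zeros(st)
    mags = (0.27, 0.36, 0.45)
    for k, (s, t) in enumerate(st.edges):
        p.a[st.index(t), st.index(s)] = mags[k % 3] * (1 if k % 2 == 0 else -1)
    for k, (s, t) in enumerate(st.edges[:4]):
        p.b[st.index(t), st.index(s)] = 0.2
    p.theta_self[:] = np.linspace(-0.25, 0.25, st.n)
    p.c[:] = np.linspace(0.32, 0.80, st.n)
    dcm.check_stability(p)
    return p


def _apply_effect(params: dcm.DCMParameters, eff: GroupEffectSpec, delta: float) -> None:
    st = params.structure
    if isinstance(eff.edge, str):
        if eff.edge not in st.regions:
            raise InvalidInputError(f"unknown region {eff.edge!r}")
        i = st.index(eff.edge)
        if eff.matrix == "A":
            params.theta_self[i] += delta
        else:
            params.b_self[i] += delta
    else:
        s, t = eff.edge
        if (s, t) not in st.edges:
            raise InvalidInputError(f"{s}->{t} is not a permitted connection")
        target = params.a if eff.matrix == "A" else params.b
        target[st.index(t), st.index(s)] += delta


def generate_group_bold(
    structure: dcm.NetworkStructure,
    base_params: dcm.DCMParameters,
    effects: Sequence[GroupEffectSpec],
    n_per_group: int,
    snr: float,
    design: dcm.DesignInput | Sequence[dcm.DesignInput],
    seed: int = 0,
    jitter_edge_sd: float = 0.05,
    hemo: Optional[dcm.HemodynamicParameters] = None,
) -> tuple[list[tuple[list[np.ndarray], int]], list[dcm.DCMParameters]]:
    """Two-group BOLD cohort with known connectivity differences.

    Subject parameters are the base set plus/minus half of each group
    effect (group code +1 / -1) plus Gaussian between-subject jitter of
    ``jitter_edge_sd`` Hz on the permitted edges.  Each subject's noise sd
    per region is the sd of their noiseless signal divided by ``snr``
    (snr <= 0 keeps the noiseless signal amplitude of the *base* model as
    reference and emits pure noise).  Returns
    ([(runs, group_code), ...], [true subject parameters, ...]).
    """
    designs = list(design) if isinstance(design, (list, tuple)) else [design]
    hemo = hemo or dcm.HemodynamicParameters()
    rng = np.random.default_rng(seed)
    mask = structure.adjacency_mask()
    datasets, truths = [], []
    for code in (-1, 1):
        for _ in range(n_per_group):
            for _attempt in range(20):
                subj = dcm.DCMParameters(
                    base_params.a.copy(), base_params.theta_self.copy(),
                    base_params.b.copy(), base_params.b_self.copy(),
                    base_params.c.copy(), structure,
                )
                for eff in effects:
                    _apply_effect(subj, eff, code * eff.effect / 2.0)
                jit = rng.normal(0.0, jitter_edge_sd, size=mask.sum())
                subj.a[mask] += jit
                try:
                    dcm.check_stability(subj)
                    break
                except StabilityError:
                    continue
            else:
                raise StabilityError(0.0)
            runs = []
            for d in designs:
                clean = dcm.bold_forward(subj, hemo, d, noise_sd=0.0)
                if snr > 0:
                    sd = clean.std(axis=0) / snr
                    noise = rng.normal(0.0, 1.0, size=clean.shape) * sd
                    runs.append(clean + noise)
                else:
                    ref = dcm.bold_forward(base_params, hemo, d, noise_sd=0.0).std(axis=0)
                    runs.append(rng.normal(0.0, 1.0, size=clean.shape) * ref)
            datasets.append((runs, code))
            truths.append(subj)
    return datasets, truths
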