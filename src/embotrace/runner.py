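"""Monte Carlo release sampling and experiment/campaign orchestration.

One *experiment* is a (stenosis model, release source) pair: roughly 5,500
emboli released either from a carotid stenosis wall or from the aortic root
face, integrated through the stitched periodic flow field over 10 cardiac
cycles, with a single 10-cycle extension whenever more than 10% of the batch
has not yet reached an outlet.  The default 30-model family yields 78
experiments (~429,000 emboli).

Release protocol: carotid emboli start uniformly over the stenosis-length
wall patch, offset inward by one embolus radius (so they are tangent to the
wall, never intersecting it); cardiogenic emboli start uniformly over the
aortic-root inlet disc, inset from the rim by the embolus radius.  Release
times are uniform over one cardiac cycle and the initial velocity is the
local fluid velocity.  Everything is reproducible from the experiment seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import hemodynamics as hemo
from . import transport as tp
from .vasculature import (
    ConfigurationError,
    ExperimentSpec,
    ModelSpec,
    NetworkTopology,
    build_baseline_network,
    build_model_network,
    enumerate_experiments,
    enumerate_models,
)

__all__ = [
    "RunPolicy",
    "ReleaseSample",
    "DistributionRecord",
    "sample_release",
    "stitch_cycles",
    "run_experiment",
    "run_campaign",
]


@dataclass(frozen=True)
class RunPolicy:
    """Campaign-level numerical policy."""

    n_per_source: int = 5500
    base_cycles: int = 10
    extension_cycles: int = 10
    unresolved_threshold: float = 0.10
    dt: float = 5.0e-5  # s
    seed: int = 0

    def integration_policy(self) -> tp.IntegrationPolicy:
        return tp.IntegrationPolicy(
            dt=self.dt,
            base_cycles=self.base_cycles,
            extension_cycles=self.extension_cycles,
            unresolved_threshold=self.unresolved_threshold,
        )


@dataclass
class ReleaseSample:
    """One embolus release: position (mm), time (s in cycle 1), source."""

    position: np.ndarray
    release_time: float
    source: str
    segment: str


@dataclass
class DistributionRecord:
    """Per-experiment source-to-destination tally."""

    experiment: str
    model_label: str
    source: str
    n_released: int
    outlet_counts: Dict[str, int]
    unresolved: int
    extended: bool
    above_threshold_after_extension: bool
    seed: int
    cca_entries: Dict[str, int] = field(default_factory=dict)

    def fractions(self) -> Dict[str, float]:
        out = {k: v / self.n_released for k, v in self.outlet_counts.items()}
        out["unresolved"] = self.unresolved / self.n_released
        return out

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DistributionRecord":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Release sampling
# ---------------------------------------------------------------------------

def _disc_frame(t_hat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    e1 = np.cross(t_hat, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1.0e-6:
        e1 = np.cross(t_hat, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(t_hat, e1)


def sample_release(
    source: str,
    network: NetworkTopology,
    field: tp.VelocityField,
    n: int,
    radius: float,
    seed: int,
    period: Optional[float] = None,
) -> List[ReleaseSample]:
    """Draw release positions and times for one experiment.

    Carotid sources sample the stenosis-length wall surface (area element
    proportional to the local circumference) offset inward by the embolus
    radius; the cardiogenic source samples the aortic-root inlet disc of
    radius ``R_inlet - radius``.  Identical seeds give identical samples.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    period = field.period if period is None else period
    rng = np.random.default_rng(seed)
    samples: List[ReleaseSample] = []
    if source == "cardiogenic":
        sid = "aortic_root"
        c, t_hat, R = field.section_frame(sid, 1.0)
        e1, e2 = _disc_frame(t_hat)
        rr = (R - radius) * np.sqrt(rng.uniform(0.0, 1.0, n))
        ang = rng.uniform(0.0, 2.0 * np.pi, n)
        times = rng.uniform(0.0, period, n)
        for r_, a_, t0 in zip(rr, ang, times):
            pos = c + r_ * (np.cos(a_) * e1 + np.sin(a_) * e2)
            samples.append(ReleaseSample(pos, float(t0), source, sid))
        return samples

    side = {"left_carotid": "left", "right_carotid": "right"}.get(source)
    if side is None:
        raise ConfigurationError(f"unknown release source {source!r}")
    sid = f"{side[0]}_internal_carotid"
    seg = network.segments[sid]
    if seg.occluded:
        raise ConfigurationError(
            f"cannot release from the occluded {side} carotid"
        )
    sten = seg.stenosis
    if sten is not None:
        s_lo, s_hi = sten.s_start, sten.s_start + sten.length
    else:  # no stenosis: release along a default proximal wall patch
        s_lo, s_hi = 8.0, min(28.0, seg.length - 2.0)
    # inverse-CDF sampling of s with surface-area weight ~ R(s)
    s_grid = np.linspace(s_lo, s_hi, 200)
    w = np.array([seg.radius_at(s) for s in s_grid])
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    ss = np.interp(rng.uniform(0.0, 1.0, n), cdf, s_grid)
    ang = rng.uniform(0.0, 2.0 * np.pi, n)
    times = rng.uniform(0.0, period, n)
    for s_, a_, t0 in zip(ss, ang, times):
        c, t_hat, R = field.section_frame(sid, float(s_))
        e1, e2 = _disc_frame(t_hat)
        rho = max(R - radius, 1.0e-3)
        pos = c + rho * (np.cos(a_) * e1 + np.sin(a_) * e2)
        samples.append(ReleaseSample(pos, float(t0), source, sid))
    return samples


def stitch_cycles(field: tp.VelocityField, n_cycles: int) -> tp.VelocityField:
    """Extend the periodic single-cycle field to an n-cycle horizon.

    The flow has no cycle-to-cycle variation, so stitching is exact periodic
    repetition: ``u(x, t + T) = u(x, t)`` for every stitched time.
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    return field.with_horizon(n_cycles * field.period)


# ---------------------------------------------------------------------------
# Experiment and campaign execution
# ---------------------------------------------------------------------------

def run_experiment(
    spec: ExperimentSpec,
    network: NetworkTopology,
    solution: hemo.FlowSolution,
    fluid: hemo.FluidProperties,
    policy: RunPolicy = RunPolicy(),
    props: Optional[tp.EmbolusProperties] = None,
    keep_trajectories: bool = False,
):
    """Run one (model, source) experiment: sample, integrate, tally.

    Returns ``(DistributionRecord, trajectories)`` where ``trajectories`` is
    the list of :class:`TrajectoryRecord` (empty unless requested).
    Deterministic for a given spec.
    """
    if solution is None:
        raise ConfigurationError("flow solution missing for experiment")
    props = props or tp.EmbolusProperties()
    fld = tp.VelocityField.from_solution(solution, network, fluid)
    fld = stitch_cycles(fld, policy.base_cycles)
    n = spec.n_emboli
    samples = sample_release(spec.source, network, fld, n, props.radius_mm, spec.seed)
    pos = np.array([s.position for s in samples])
    t0s = np.array([s.release_time for s in samples])
    segs = [s.segment for s in samples]
    vels = np.array(
        [fld.velocity(p, t, segment_hint=sg) for p, t, sg in zip(pos, t0s, segs)]
    )
    records, extended = tp.integrate_batch(
        fld, pos, vels, t0s, props, fluid, policy.integration_policy(), segments=segs
    )
    counts: Dict[str, int] = {o: 0 for o in network.outlets}
    unresolved = 0
    cca = {"l_common_carotid": 0, "r_common_carotid": 0}
    for rec in records:
        if rec.exit_outlet is None:
            unresolved += 1
        else:
            counts[rec.exit_outlet] += 1
        for key in cca:
            if key in rec.segments_visited:
                cca[key] += 1
    record = DistributionRecord(
        experiment=spec.label,
        model_label=spec.model.label,
        source=spec.source,
        n_released=n,
        outlet_counts=counts,
        unresolved=unresolved,
        extended=extended,
        above_threshold_after_extension=(
            unresolved / n > policy.unresolved_threshold
        ),
        seed=spec.seed,
        cca_entries=cca,
    )
    return record, (records if keep_trajectories else [])


def _spec_hash(spec: ExperimentSpec, policy: RunPolicy) -> str:
    payload = json.dumps(
        {
            "model": spec.model.label,
            "source": spec.source,
            "n": spec.n_emboli,
            "seed": spec.seed,
            "policy": asdict(policy),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_campaign(
    out_dir,
    family_config: Optional[dict] = None,
    policy: RunPolicy = RunPolicy(),
    template_config: Optional[dict] = None,
    targets_config: Optional[dict] = None,
    fluid: Optional[hemo.FluidProperties] = None,
    waveform: Optional[hemo.CardiacWaveform] = None,
    props: Optional[tp.EmbolusProperties] = None,
    models: Optional[Sequence[ModelSpec]] = None,
    verbose: bool = False,
) -> List[DistributionRecord]:
    """Execute the full in-silico experiment campaign.

    Tunes outlet resistances once on the no-stenosis baseline and reuses
    them for every stenosis model, solves each model's pulsatile flow, runs
    every (model, source) experiment and writes one JSON record per
    experiment plus a campaign manifest.  Experiments whose record already
    exists (matching content hash) are skipped, so an interrupted campaign
    resumes.  Per-experiment failures are isolated and reported in the
    manifest; the campaign continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fluid = fluid or hemo.FluidProperties()
    waveform = waveform or hemo.CardiacWaveform()
    props = props or tp.EmbolusProperties()

    baseline = build_baseline_network(template_config)
    targets = hemo.target_flow_splits(baseline, targets_config)
    resistances = hemo.tune_outlet_resistances(baseline, targets, waveform, fluid)
    if models is None:
        models = enumerate_models(family_config)
    experiments = enumerate_experiments(models, policy.n_per_source, policy.seed)

    records: List[DistributionRecord] = []
    failures: List[Dict[str, str]] = []
    solutions: Dict[str, Tuple[NetworkTopology, hemo.FlowSolution]] = {}
    for spec in experiments:
        h = _spec_hash(spec, policy)
        path = out_dir / f"{spec.model.label}_{spec.source}_{h}.json"
        if path.exists():
            records.append(DistributionRecord.from_json(path.read_text()))
            continue
        try:
            if spec.model.label not in solutions:
                net = build_model_network(baseline, spec.model)
                sol = hemo.solve_unsteady(net, waveform, resistances, fluid)
                solutions[spec.model.label] = (net, sol)
            net, sol = solutions[spec.model.label]
            t0 = time.time()
            record, _ = run_experiment(spec, net, sol, fluid, policy, props)
            path.write_text(record.to_json())
            records.append(record)
            if verbose:
                print(
                    f"{spec.label}: unresolved "
                    f"{record.unresolved}/{record.n_released} "
                    f"({time.time() - t0:.1f}s)"
                )
        except Exception as exc:  # isolate per-experiment failures
            failures.append({"experiment": spec.label, "error": repr(exc)})
    manifest = {
        "n_experiments": len(experiments),
        "n_completed": len(records),
        "failures": failures,
        "policy": asdict(policy),
        "resistances": resistances.resistances,
        "targets": targets.fractions,
        "seeds": {e.label: e.seed for e in experiments},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return records
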