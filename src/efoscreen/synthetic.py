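"""Synthetic ensemble-docking campaigns with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes for a docking campaign over an MD run of a homotetramer:

* decoy pose scores are exchangeable noise, correlated across the three
  score types through a shared latent component;
* active pose scores are shifted (in the "better" direction) by an
  effect that grows with a frame-level *equilibration quality* — a
  sigmoid in simulation time — and differs between monomers;
* docking failures delete whole pose groups, more often at low quality
  and on designated fragile monomers, so early frames can trip the
  monomer/frame suitability filters;
* binding-pocket volumes are coupled to the same quality curve, and the
  side-chain-optimized variant inflates volumes, damps failures and
  boosts the active effect.

Everything is drawn from one seeded stream, so identical configuration
and seed give byte-identical campaigns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import (MONOMERS, SCORE_TYPES, DataError, LigandRecord,
                       PoseScoreTable)
from .trajectory import VolumeTable


def _default_frames() -> tuple:
    return tuple(range(25, 1251, 25))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic campaign.

    Defaults mirror the benchmark layout the analysis targets: a
    1000-ligand library with 20 actives screened against 50 frames
    (25–1250 ns every 25 ns) x 4 monomers x 3 score types x 10 poses.
    Effect sizes are in raw score units; the per-type decoy standard
    deviations set the scale.
    """

    n_ligands: int = 1000
    n_actives: int = 20
    frame_times: Sequence[int] = field(default_factory=_default_frames)
    n_poses: int = 10
    decoy_mean: Mapping[str, float] = field(
        default_factory=lambda: {"PS": 60.0, "CS": 40.0, "CSOPT": 42.0})
    decoy_sd: Mapping[str, float] = field(
        default_factory=lambda: {"PS": 8.0, "CS": 10.0, "CSOPT": 10.0})
    #: active shift per score type at quality 1 and monomer multiplier 1
    effect_size: Mapping[str, float] = field(
        default_factory=lambda: {"PS": 3.0, "CS": 11.0, "CSOPT": 13.0})
    #: equilibration quality: sigmoid midpoint and steepness (ns)
    quality_midpoint_ns: float = 400.0
    quality_steepness_ns: float = 150.0
    monomer_effect: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.9, "B": 1.1, "C": 1.0, "D": 0.7})
    #: docking-failure probability = base * (1 - quality) * multiplier
    failure_base: float = 0.08
    monomer_failure: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.5, "B": 0.5, "C": 0.2, "D": 3.0})
    score_type_correlation: float = 0.6
    #: side-chain-optimized variant modifiers
    optimized_volume_inflation: float = 1.39
    optimized_failure_reduction: float = 0.6
    optimized_effect_boost: float = 1.15
    #: pocket volumes: per-monomer base (Å³), quality coupling, noise sd
    volume_base: Mapping[str, float] = field(
        default_factory=lambda: {"A": 320.0, "B": 560.0,
                                 "C": 470.0, "D": 400.0})
    volume_coupling: float = 0.35
    volume_noise_sd: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_actives < self.n_ligands:
            raise DataError("need 0 < n_actives < n_ligands")
        if self.n_poses < 1:
            raise DataError("n_poses must be >= 1")
        if not 0 <= self.failure_base <= 1:
            raise DataError("failure_base must lie in [0, 1]")
        if not 0 <= self.score_type_correlation < 1:
            raise DataError("score_type_correlation must lie in [0, 1)")
        if any(v < 0 for v in self.effect_size.values()):
            raise DataError("effect sizes must be >= 0")
        if len(self.frame_times) == 0 or min(self.frame_times) <= 0:
            raise DataError("frame_times must be positive")

    def quality(self, frame_ns) -> np.ndarray:
        """Equilibration quality in (0, 1): sigmoid in simulation time."""
        t = np.asarray(frame_ns, dtype=float)
        return 1.0 / (1.0 + np.exp(
            -(t - self.quality_midpoint_ns) / self.quality_steepness_ns))


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    frame_quality: dict
    #: (variant, frame_ns, monomer, score_type) -> active shift in
    #: decoy-sd units
    channel_effect: dict
    #: set of (variant, frame_ns, monomer, ligand_id) failure events
    failures: set
    volume_coupling: float

    def top_channels(self, variant: str, frame_ns: int,
                     decile: float = 0.1) -> set:
        """(monomer, score_type) pairs in the top effect decile of one
        frame's variable pool."""
        effects = {(m, s): e for (v, f, m, s), e in
                   self.channel_effect.items()
                   if v == variant and f == frame_ns}
        values = sorted(set(effects.values()), reverse=True)
        cut = values[max(0, int(np.ceil(len(values) * decile)) - 1)]
        return {k for k, e in effects.items() if e >= cut}


@dataclass
class CampaignData:
    """A generated campaign: both variants, labels, volumes, truth."""

    raw: PoseScoreTable
    optimized: PoseScoreTable
    labels: pd.DataFrame
    volumes: VolumeTable
    truth: GroundTruth
    config: GeneratorConfig

    @property
    def ligand_records(self) -> list:
        return [LigandRecord(r.ligand_id, bool(r.active))
                for r in self.labels.itertuples()]


def _variant_table(cfg: GeneratorConfig, rng: np.random.Generator,
                   variant: str, is_active: np.ndarray,
                   ligand_ids: np.ndarray, truth: GroundTruth
                   ) -> PoseScoreTable:
    frames = np.asarray(cfg.frame_times, dtype=int)
    F, M, L, S, P = (len(frames), len(MONOMERS), cfg.n_ligands,
                     len(SCORE_TYPES), cfg.n_poses)
    q = cfg.quality(frames)  # (F,)
    boost = cfg.optimized_effect_boost if variant == "OPTIMIZED" else 1.0
    fail_scale = (cfg.optimized_failure_reduction
                  if variant == "OPTIMIZED" else 1.0)

    rho = cfg.score_type_correlation
    z_common = rng.standard_normal((F, M, L, 1, P))
    z_own = rng.standard_normal((F, M, L, S, P))
    z = np.sqrt(rho) * z_common + np.sqrt(1.0 - rho) * z_own

    mean = np.array([cfg.decoy_mean[s] for s in SCORE_TYPES])
    sd = np.array([cfg.decoy_sd[s] for s in SCORE_TYPES])
    delta = np.array([cfg.effect_size[s] for s in SCORE_TYPES])
    mono_mult = np.array([cfg.monomer_effect[m] for m in MONOMERS])

    values = mean[None, None, None, :, None] + sd[None, None, None, :, None] * z
    shift = (boost * delta[None, None, None, :] *
             q[:, None, None, None] * mono_mult[None, :, None, None] *
             is_active[None, None, :, None])
    values = values + shift[..., None]

    # failures: whole (frame, monomer, ligand) pose groups vanish
    p_fail = (cfg.failure_base * fail_scale *
              (1.0 - q)[:, None, None] *
              np.array([cfg.monomer_failure[m]
                        for m in MONOMERS])[None, :, None])
    p_fail = np.clip(np.broadcast_to(p_fail, (F, M, L)), 0.0, 1.0)
    failed = rng.random((F, M, L)) < p_fail

    for (fi, mi, li) in zip(*np.nonzero(failed)):
        truth.failures.add((variant, int(frames[fi]), MONOMERS[mi],
                            str(ligand_ids[li])))
    for fi, f in enumerate(frames):
        for mi, m in enumerate(MONOMERS):
            for si, s in enumerate(SCORE_TYPES):
                truth.channel_effect[(variant, int(f), m, s)] = float(
                    boost * delta[si] * q[fi] * mono_mult[mi] / sd[si])

    keep = ~failed[:, :, :, None, None]
    keep = np.broadcast_to(keep, values.shape)

    fi, mi, li, si, pi = np.nonzero(keep)
    df = pd.DataFrame({
        "ligand_id": ligand_ids[li],
        "frame_ns": frames[fi].astype(np.int32),
        "monomer": pd.Categorical.from_codes(mi, list(MONOMERS)),
        "score_type": pd.Categorical.from_codes(si, list(SCORE_TYPES)),
        "pose": (pi + 1).astype(np.int16),
        "value": values[fi, mi, li, si, pi],
    })
    return PoseScoreTable(df=df, variant=variant, pose_budget=cfg.n_poses)


def generate_campaign(config: GeneratorConfig | None = None,
                      seed: int | None = None) -> CampaignData:
    """Draw a full two-variant campaign from one seeded stream."""
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    # neutral ids: the ligand-id tie-break must not correlate with
    # activity, so the active subset is drawn at random over the library
    n_digits = len(str(cfg.n_ligands))
    ligand_ids = np.array(
        [f"LIG{str(i + 1).zfill(n_digits)}" for i in range(cfg.n_ligands)],
        dtype=object)
    active_idx = rng.choice(cfg.n_ligands, size=cfg.n_actives, replace=False)
    is_active = np.zeros(cfg.n_ligands, dtype=float)
    is_active[active_idx] = 1.0
    labels = pd.DataFrame({"ligand_id": ligand_ids,
                           "active": is_active.astype(int)})

    frames = np.asarray(cfg.frame_times, dtype=int)
    truth = GroundTruth(
        frame_quality={int(f): float(qv)
                       for f, qv in zip(frames, cfg.quality(frames))},
        channel_effect={}, failures=set(),
        volume_coupling=cfg.volume_coupling)

    raw = _variant_table(cfg, rng, "RAW", is_active, ligand_ids, truth)
    opt = _variant_table(cfg, rng, "OPTIMIZED", is_active, ligand_ids, truth)

    q = cfg.quality(frames)
    vol_rows = []
    for variant, inflation in (("RAW", 1.0),
                               ("OPTIMIZED", cfg.optimized_volume_inflation)):
        for m in MONOMERS:
            base = cfg.volume_base[m]
            noise = rng.normal(0.0, cfg.volume_noise_sd, size=len(frames))
            vols = inflation * (base * (1.0 + cfg.volume_coupling * q)
                                + noise)
            for f, v in zip(frames, vols):
                vol_rows.append((int(f), m, variant, max(float(v), 0.0)))
    volumes = VolumeTable(pd.DataFrame(
        vol_rows, columns=["frame_ns", "monomer", "variant", "volume"]))

    return CampaignData(raw=raw, optimized=opt, labels=labels,
                        volumes=volumes, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Hand-sized deterministic fixtures with documented expected outcomes.

FIXTURE_NAMES = ("tiny-separable", "two-complementary-channels",
                 "heavy-failures")


def generate_fixture_instance(name: str) -> CampaignData:
    """Small deterministic campaigns for exact pipeline checks.

    - ``tiny-separable``: 40 ligands (4 active), one frame; the CS/BEST
      channel of monomer B separates actives perfectly
      (``expected_channel`` in config provenance).
    - ``two-complementary-channels``: two channels each ranking half the
      actives on top; the two-term model beats both one-term models.
    - ``heavy-failures``: frame 50 loses monomers A, C and D to active
      docking failures (frame discarded); frame 100 loses only D.
    """
    if name == "tiny-separable":
        cfg = GeneratorConfig(
            n_ligands=40, n_actives=4, frame_times=(100,), n_poses=3,
            effect_size={"PS": 0.0, "CS": 40.0, "CSOPT": 0.0},
            monomer_effect={"A": 0.0, "B": 1.0, "C": 0.0, "D": 0.0},
            failure_base=0.0, quality_midpoint_ns=-1000.0,
            quality_steepness_ns=1.0, seed=11)
        return generate_campaign(cfg)
    if name == "two-complementary-channels":
        # built by hand: 30 ligands, 4 actives, one frame/monomer,
        # CS best separates actives 1-2, CSOPT best separates 3-4
        n, n_act = 30, 4
        ids = [f"L{str(i).zfill(2)}" for i in range(1, n + 1)]
        # actives scattered through the id range so that id-order
        # tie-breaking carries no activity information
        active_idx = (4, 11, 18, 25)
        rng = np.random.default_rng(7)
        rows = []
        for st in ("CS", "CSOPT"):
            vals = rng.normal(0.0, 1.0, size=n)
            boosted = active_idx[:2] if st == "CS" else active_idx[2:]
            for i in boosted:
                vals[i] += 12.0
            for i, lig in enumerate(ids):
                rows.append((lig, 100, "A", st, 1, float(vals[i])))
        df = pd.DataFrame(rows, columns=["ligand_id", "frame_ns", "monomer",
                                         "score_type", "pose", "value"])
        labels = pd.DataFrame({
            "ligand_id": ids,
            "active": [1 if i in active_idx else 0 for i in range(n)]})
        table = PoseScoreTable(df=df, variant="RAW", pose_budget=1)
        truth = GroundTruth(frame_quality={100: 1.0}, channel_effect={
            ("RAW", 100, "A", "CS"): 12.0,
            ("RAW", 100, "A", "CSOPT"): 12.0},
            failures=set(), volume_coupling=0.0)
        vols = VolumeTable(pd.DataFrame(
            [(100, m, "RAW", 400.0) for m in MONOMERS],
            columns=["frame_ns", "monomer", "variant", "volume"]))
        return CampaignData(raw=table, optimized=table, labels=labels,
                            volumes=vols, truth=truth,
                            config=GeneratorConfig(n_ligands=n,
                                                   n_actives=n_act,
                                                   frame_times=(100,)))
    if name == "heavy-failures":
        n, n_act = 30, 6
        ids = [f"L{str(i).zfill(2)}" for i in range(1, n + 1)]
        actives = ids[:n_act]
        rng = np.random.default_rng(3)
        # monomers losing >3 actives per frame (frame -> {monomer: failed})
        planted = {50: {"A": actives[:4], "C": actives[:5],
                        "D": actives[:6]},
                   100: {"D": actives[:4]}}
        rows = []
        for f in (50, 100):
            for m in MONOMERS:
                failed = set(planted.get(f, {}).get(m, []))
                for lig in ids:
                    if lig in failed:
                        continue
                    rows.append((lig, f, m, "CS", 1,
                                 float(rng.normal(0, 1)) +
                                 (3.0 if lig in actives else 0.0)))
        df = pd.DataFrame(rows, columns=["ligand_id", "frame_ns", "monomer",
                                         "score_type", "pose", "value"])
        labels = pd.DataFrame({"ligand_id": ids,
                               "active": [1] * n_act + [0] * (n - n_act)})
        table = PoseScoreTable(df=df, variant="RAW", pose_budget=1)
        truth = GroundTruth(
            frame_quality={50: 0.5, 100: 0.5}, channel_effect={},
            failures={("RAW", f, m, lig)
                      for f, per in planted.items()
                      for m, ligs in per.items() for lig in ligs},
            volume_coupling=0.0)
        vols = VolumeTable(pd.DataFrame(
            [(f, m, "RAW", 400.0) for f in (50, 100) for m in MONOMERS],
            columns=["frame_ns", "monomer", "variant", "volume"]))
        return CampaignData(raw=table, optimized=table, labels=labels,
                            volumes=vols, truth=truth,
                            config=GeneratorConfig(n_ligands=n,
                                                   n_actives=n_act,
                                                   frame_times=(50, 100)))
    raise DataError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
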