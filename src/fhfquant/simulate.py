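"""Seeded generators with known ground truth for every analysis stage.

Three families of synthetic data are produced, mirroring the three kinds
of measurement the analysis modules consume:

* **Spectral counts** — peptide-level evidence tables for a 4-replicate
  bait condition versus a 4-replicate cytoplasmic-control condition, with
  planted true interactors, shared peptides, and optional per-replicate
  dropout.  Peptide counts are Poisson with protein-level rate
  proportional to abundance x length, the simplest model that reproduces
  the mean-variance behavior spectral counting assumes.
* **Single-molecule traces** — events land on a microtubule as a Poisson
  process and are processive (piecewise-constant-velocity runs with
  planted pauses), diffusive (random walks guaranteed to make >0.6-um
  excursions in both directions), or static.  Localization noise is added
  per frame.  A ground-truth event log is emitted alongside the trace
  table so recovery tests never re-derive truth from the data.
* **ROI measurements and tubule tracks** — paired centrosome/whole-cell
  intensities with a known accumulation ratio, and per-cell tubule tracks
  with known qualifying counts.

Every generator is deterministic given its config (seed included): the
same config yields byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio

__all__ = [
    "ProteomeSimConfig",
    "MotilitySimConfig",
    "RoiSimConfig",
    "TubuleSimConfig",
    "ProteomeSim",
    "TraceSim",
    "simulate_spectral_counts",
    "simulate_traces",
    "simulate_roi_measurements",
    "simulate_tubule_tracks",
    "expected_processive_landing_rate",
    "write_proteome_sim",
    "write_trace_sim",
    "write_roi_sim",
]


# --------------------------------------------------------------------------
# proteomics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Bait-vs-control spectral-count simulation parameters.

    ``baseline_count_mean`` is the expected total spectral count per
    background protein per replicate (scaled by relative protein length);
    true interactors get ``enrichment_factor`` times that rate in bait
    replicates.  ``dropout_prob`` is the chance a true interactor yields
    zero counts in any given replicate (either condition).
    """

    n_background_proteins: int = 500
    n_true_interactors: int = 20
    n_replicates_bait: int = 4
    n_replicates_control: int = 4
    baseline_count_mean: float = 10.0
    enrichment_factor: float = 5.0
    shared_peptide_fraction: float = 0.1
    dropout_prob: float = 0.1
    protein_length_range: tuple[int, int] = (100, 1000)
    seed: int = 0

    def __post_init__(self):
        if self.n_background_proteins < 1 or self.n_true_interactors < 0:
            raise ValueError("protein counts must be positive")
        if self.n_replicates_bait < 2 or self.n_replicates_control < 2:
            raise ValueError("need >=2 replicates per condition")
        if self.baseline_count_mean <= 0:
            raise ValueError("baseline_count_mean must be positive")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if not 0 <= self.shared_peptide_fraction < 1:
            raise ValueError("shared_peptide_fraction must be in [0, 1)")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid protein_length_range")


@dataclass
class ProteomeSim:
    """Simulated spectral-count experiment with ground truth."""

    bait: pd.DataFrame  # peptide evidence, bait condition
    control: pd.DataFrame  # peptide evidence, control condition
    proteins: pd.DataFrame  # protein_id, length_aa
    true_interactors: set
    config: ProteomeSimConfig


def simulate_spectral_counts(config: ProteomeSimConfig) -> ProteomeSim:
    """Draw peptide-level spectral counts for bait and control conditions.

    Each protein's expected total count per replicate is
    ``baseline_count_mean x length / mean(length)``, multiplied by
    ``enrichment_factor`` for true interactors in bait replicates, split
    evenly over that protein's peptide slots; each peptide's count is then
    Poisson.  A shared peptide (two parent proteins) draws
    Poisson(sum of its parents' per-slot rates).
    """
    rng = np.random.default_rng(config.seed)
    ni, nb = config.n_true_interactors, config.n_background_proteins
    n_prot = ni + nb
    lo, hi = config.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=n_prot)
    ids = [f"INT{i:04d}" for i in range(ni)] + [f"BG{i:04d}" for i in range(nb)]
    is_interactor = np.zeros(n_prot, dtype=bool)
    is_interactor[:ni] = True

    base_rate = config.baseline_count_mean * lengths / lengths.mean()
    n_pep = np.maximum(2, lengths // 200)
    n_unique = int(n_pep.sum())
    f = config.shared_peptide_fraction
    n_shared = int(round(f / (1 - f) * n_unique)) if f > 0 else 0
    if n_shared > 0 and n_prot < 2:
        raise ValueError("shared peptides require >=2 proteins")
    shared_members = np.empty((n_shared, 2), dtype=int)
    for s in range(n_shared):
        shared_members[s] = rng.choice(n_prot, size=2, replace=False)
    slots = n_pep.astype(float)
    for a, b in shared_members:
        slots[a] += 1
        slots[b] += 1

    pidx = np.repeat(np.arange(n_prot), n_pep)

    def draw_condition(n_reps: int, bait: bool) -> pd.DataFrame:
        rate = np.tile(base_rate[:, None], (1, n_reps)).astype(float)
        if bait:
            rate[is_interactor] *= config.enrichment_factor
        if config.dropout_prob > 0 and ni > 0:
            drop = rng.random((ni, n_reps)) < config.dropout_prob
            rate[:ni][drop] = 0.0
        lam = rate / slots[:, None]
        counts_u = rng.poisson(lam[pidx])
        rows = {
            "peptide_id": [f"pepu_{i:05d}" for i in range(n_unique)],
            "protein_ids": [ids[p] for p in pidx],
        }
        if n_shared > 0:
            lam_s = lam[shared_members[:, 0]] + lam[shared_members[:, 1]]
            counts_s = rng.poisson(lam_s)
            rows["peptide_id"] = rows["peptide_id"] + [
                f"peps_{i:05d}" for i in range(n_shared)
            ]
            rows["protein_ids"] = rows["protein_ids"] + [
                f"{ids[a]};{ids[b]}" for a, b in shared_members
            ]
            counts = np.vstack([counts_u, counts_s])
        else:
            counts = counts_u
        df = pd.DataFrame(rows)
        for r in range(n_reps):
            df[f"rep{r + 1}"] = counts[:, r]
        return df

    control = draw_condition(config.n_replicates_control, bait=False)
    bait = draw_condition(config.n_replicates_bait, bait=True)
    proteins = pd.DataFrame({"protein_id": ids, "length_aa": lengths})
    return ProteomeSim(
        bait=bait,
        control=control,
        proteins=proteins,
        true_interactors=set(ids[:ni]),
        config=config,
    )


# --------------------------------------------------------------------------
# single-molecule traces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MotilitySimConfig:
    """Single-molecule trace simulation parameters.

    Events land on the microtubule as a Poisson process with rate
    ``landing_rate_true x mt_length`` per second and are diffusive, static,
    or processive according to the class fractions.  Processive runs have
    exponential length (mean ``run_length_mean``, floored at
    ``min_run_length`` so every planted run exceeds the 0.6-um taxonomy
    scale), normal velocity, and pauses planted as a Poisson process along
    the run (``pause_rate_true`` per um).  Pause durations are drawn as
    (3-frame minimum + exponential remainder) so every planted pause is in
    principle detectable at the movie's frame interval; shorter pauses
    would be unrecoverable by construction.
    """

    n_movies: int = 50
    movie_duration: float = 180.0  # s; 0.4-s frames for 3 min
    frame_interval: float = 0.4  # s
    mt_length: float = 25.0  # um
    landing_rate_true: float = 2.5e-3  # events / (um * s)
    velocity_mean: float = 0.8  # um/s
    velocity_sd: float = 0.1  # um/s
    run_length_mean: float = 4.0  # um
    min_run_length: float = 0.8  # um
    pause_rate_true: float = 0.2  # pauses / um of run
    pause_duration_mean: float = 2.0  # s
    diffusive_fraction: float = 0.1
    static_fraction: float = 0.1
    localization_noise_sd: float = 0.02  # um
    colocalization_prob: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.frame_interval >= self.movie_duration:
            raise ValueError("frame_interval must be smaller than movie_duration")
        if self.n_movies < 1:
            raise ValueError("n_movies must be positive")
        if self.mt_length <= 0:
            raise ValueError("mt_length must be positive")
        if self.landing_rate_true < 0:
            raise ValueError("landing_rate_true must be >= 0")
        if self.velocity_mean <= 0:
            raise ValueError("velocity_mean must be positive")
        for frac in (self.diffusive_fraction, self.static_fraction, self.colocalization_prob):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.diffusive_fraction + self.static_fraction > 1:
            raise ValueError("diffusive_fraction + static_fraction must be <= 1")
        if self.run_length_mean <= 0 or not 0 < self.min_run_length <= self.run_length_mean:
            raise ValueError("invalid run-length parameters")
        if self.pause_rate_true < 0 or self.pause_duration_mean < 0:
            raise ValueError("pause parameters must be >= 0")
        if self.localization_noise_sd < 0 or self.velocity_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_duration / self.frame_interval))

    @property
    def min_pause_duration(self) -> float:
        """Shortest planted pause: one frame above the 3-frame detection scale."""
        return 4 * self.frame_interval


@dataclass
class TraceSim:
    """Simulated trace table plus ground-truth event log."""

    traces: pd.DataFrame
    truth: pd.DataFrame
    config: MotilitySimConfig


def _has_bidirectional_excursion(path: np.ndarray, threshold: float) -> bool:
    running_min = np.minimum.accumulate(path)
    running_max = np.maximum.accumulate(path)
    return (
        float(np.max(path - running_min)) > threshold
        and float(np.max(running_max - path)) > threshold
    )


def _processive_breakpoints(cfg, rng, x0: float):
    """Piecewise-linear (time, position) breakpoints for one processive run."""
    v = rng.normal(cfg.velocity_mean, cfg.velocity_sd)
    while v <= 0.05 * cfg.velocity_mean:
        v = rng.normal(cfg.velocity_mean, cfg.velocity_sd)
    ell = cfg.min_run_length + rng.exponential(cfg.run_length_mean - cfg.min_run_length)
    ell = min(ell, cfg.mt_length - x0)  # motor falls off at the microtubule end
    n_pauses = rng.poisson(cfg.pause_rate_true * ell) if ell > 0 else 0
    pause_pos = np.sort(rng.uniform(0.0, ell, size=n_pauses))
    excess = max(cfg.pause_duration_mean - cfg.min_pause_duration, 1e-9)
    pause_dur = cfg.min_pause_duration + rng.exponential(excess, size=n_pauses)
    t_bp, x_bp = [0.0], [x0]
    t, prev_d = 0.0, 0.0
    for pd_, dur in zip(pause_pos, pause_dur):
        t += (pd_ - prev_d) / v
        t_bp.append(t)
        x_bp.append(x0 + pd_)
        t += dur
        t_bp.append(t)
        x_bp.append(x0 + pd_)
        prev_d = pd_
    t += (ell - prev_d) / v
    t_bp.append(t)
    x_bp.append(x0 + ell)
    return np.array(t_bp), np.array(x_bp), v, ell, n_pauses


def simulate_traces(config: MotilitySimConfig) -> TraceSim:
    """Generate single-molecule traces with a ground-truth event log.

    Events with fewer than two in-movie frames are dropped from both the
    trace table and the truth log, so the two always describe the same
    event set.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval
    n_frames = cfg.n_frames
    trace_rows = []
    truth_rows = []
    for m in range(cfg.n_movies):
        n_events = rng.poisson(cfg.landing_rate_true * cfg.mt_length * cfg.movie_duration)
        for k in range(n_events):
            event_id = f"m{m:03d}_e{k:03d}"
            t0 = rng.uniform(0.0, cfg.movie_duration)
            u = rng.random()
            if u < cfg.diffusive_fraction:
                event_class = "diffusive"
            elif u < cfg.diffusive_fraction + cfg.static_fraction:
                event_class = "static"
            else:
                event_class = "processive"

            f0 = int(math.ceil(t0 / dt))
            velocity_true = np.nan
            run_length_true = np.nan
            n_pauses_true = 0
            colocalized = False
            channel2 = None

            if event_class == "processive":
                x0 = rng.uniform(0.0, cfg.mt_length)
                t_bp, x_bp, v, ell, n_pauses = _processive_breakpoints(cfg, rng, x0)
                t_end = min(t0 + t_bp[-1], cfg.movie_duration)
                f1 = min(int(math.floor(t_end / dt)), n_frames - 1)
                if f1 - f0 < 1:
                    continue
                frame_times = np.arange(f0, f1 + 1) * dt
                positions = np.interp(frame_times - t0, t_bp, x_bp)
                velocity_true = v
                run_length_true = ell
                n_pauses_true = n_pauses
                colocalized = bool(rng.random() < cfg.colocalization_prob)
                n = len(positions)
                channel2 = np.zeros(n, dtype=bool)
                if colocalized:
                    span = max(1, int(round(rng.uniform(0.5, 1.0) * n)))
                    start = int(rng.integers(0, n - span + 1))
                    channel2[start : start + span] = True
            elif event_class == "diffusive":
                n_f = max(20, int(rng.exponential(12.0 / dt)))
                f1 = min(f0 + n_f, n_frames - 1)
                if f1 - f0 < 1:
                    continue
                n = f1 - f0 + 1
                path = None
                for _ in range(100):
                    cand = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, 0.18, n - 1))])
                    if _has_bidirectional_excursion(cand, 0.6):
                        path = cand
                        break
                if path is None:  # very short window; accept the last draw
                    path = cand
                lo_off, hi_off = -path.min(), cfg.mt_length - path.max()
                offset = rng.uniform(lo_off, hi_off) if hi_off > lo_off else cfg.mt_length / 2
                positions = path + offset
            else:  # static
                n_f = max(2, int(rng.exponential(8.0 / dt)))
                f1 = min(f0 + n_f, n_frames - 1)
                if f1 - f0 < 1:
                    continue
                n = f1 - f0 + 1
                positions = np.full(n, rng.uniform(0.0, cfg.mt_length))

            n = len(positions)
            if cfg.localization_noise_sd > 0:
                positions = positions + rng.normal(0.0, cfg.localization_noise_sd, n)
            positions = np.clip(positions, 0.0, cfg.mt_length)
            frames = np.arange(f0, f0 + n)
            if channel2 is None:
                channel2 = np.zeros(n, dtype=bool)

            for i in range(n):
                trace_rows.append(
                    (
                        event_id,
                        f"m{m:03d}",
                        int(frames[i]),
                        frames[i] * dt,
                        positions[i],
                        bool(channel2[i]),
                    )
                )
            truth_rows.append(
                {
                    "event_id": event_id,
                    "movie_id": f"m{m:03d}",
                    "event_class": event_class,
                    "velocity_true": velocity_true,
                    "run_length_true": run_length_true,
                    "n_pauses_true": n_pauses_true,
                    "first_frame": int(frames[0]),
                    "last_frame": int(frames[-1]),
                    "qualifies_landing": bool(
                        event_class == "processive"
                        and frames[0] > 0
                        and frames[-1] < n_frames - 1
                    ),
                    "colocalized": colocalized,
                }
            )
    traces = pd.DataFrame(
        trace_rows,
        columns=["event_id", "movie_id", "frame", "time_s", "position_um", "channel2_present"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "event_id",
            "movie_id",
            "event_class",
            "velocity_true",
            "run_length_true",
            "n_pauses_true",
            "first_frame",
            "last_frame",
            "qualifies_landing",
            "colocalized",
        ],
    )
    return TraceSim(traces=traces, truth=truth, config=cfg)


def expected_processive_landing_rate(config: MotilitySimConfig) -> float:
    """Processive landing rate the analyzer is expected to observe.

    Starting from ``landing_rate_true`` (all landings), this applies the
    processive class fraction, the loss of events landing within the
    0.6-um taxonomy scale of the microtubule plus end (their truncated
    runs fall below the static threshold), and movie-end censoring: the
    counting rule requires an event to end before the last frame, so
    landings in roughly the final mean-event-duration of the movie are
    excluded by definition.
    """
    cfg = config
    p_proc = 1.0 - cfg.diffusive_fraction - cfg.static_fraction
    p_edge = min(1.0, 0.6 / cfg.mt_length)
    e_run = cfg.run_length_mean
    cv2 = (cfg.velocity_sd / cfg.velocity_mean) ** 2
    e_inv_v = (1.0 + cv2) / cfg.velocity_mean
    mean_pause = max(cfg.pause_duration_mean, cfg.min_pause_duration)
    e_dur = e_run * e_inv_v + cfg.pause_rate_true * e_run * mean_pause
    censor = max(0.0, 1.0 - e_dur / cfg.movie_duration)
    return cfg.landing_rate_true * p_proc * (1.0 - p_edge) * censor


# --------------------------------------------------------------------------
# ROI measurements and tubule tracks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiSimConfig:
    """Centrosome/whole-cell ROI simulation parameters.

    ``accumulation_true`` is the ground-truth area-normalized enrichment
    ratio; before noise, each cell's centrosomal intensity fraction is
    ``accumulation_true x centrosome_area_fraction``, which must not
    exceed 1 (more signal than the whole cell is impossible geometry).
    """

    n_cells_per_group: int = 30
    centrosome_area_fraction: float = 0.05
    accumulation_true: float = 2.0
    intensity_noise_cv: float = 0.1
    group: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if self.n_cells_per_group < 1:
            raise ValueError("n_cells_per_group must be positive")
        if not 0 < self.centrosome_area_fraction < 1:
            raise ValueError("centrosome_area_fraction must be in (0, 1)")
        if self.accumulation_true <= 0:
            raise ValueError("accumulation_true must be positive")
        if self.accumulation_true * self.centrosome_area_fraction > 1:
            raise ValueError(
                "impossible geometry: accumulation_true x centrosome_area_fraction > 1"
            )
        if self.intensity_noise_cv < 0:
            raise ValueError("intensity_noise_cv must be >= 0")


def simulate_roi_measurements(config: RoiSimConfig) -> pd.DataFrame:
    """Draw paired centrosome/whole-cell ROI measurements for one group."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells_per_group
    whole_area = rng.uniform(15000.0, 30000.0, n)
    cent_area = cfg.centrosome_area_fraction * whole_area
    whole_intensity = 1e5 * np.clip(1.0 + cfg.intensity_noise_cv * rng.standard_normal(n), 0.05, None)
    frac = cfg.accumulation_true * cfg.centrosome_area_fraction * (
        1.0 + cfg.intensity_noise_cv * rng.standard_normal(n)
    )
    frac = np.clip(frac, 0.0, 1.0)  # centrosome signal cannot exceed the cell's
    return pd.DataFrame(
        {
            "cell_id": [f"{cfg.group}_c{i:03d}" for i in range(n)],
            "group": cfg.group,
            "centrosome_intensity": frac * whole_intensity,
            "whole_cell_intensity": whole_intensity,
            "centrosome_area": cent_area,
            "whole_cell_area": whole_area,
        }
    )


@dataclass(frozen=True)
class TubuleSimConfig:
    """Per-cell tubule track simulation parameters.

    Each cell gets Poisson numbers of qualifying motile tubules (moved,
    length > 1 um), non-moving tubules, and sub-micron motile puncta; the
    latter two are planted disqualifiers.
    """

    n_cells: int = 50
    motile_per_cell_mean: float = 6.0
    immotile_per_cell_mean: float = 2.0
    puncta_per_cell_mean: float = 2.0
    length_excess_mean: float = 1.5  # um beyond the 1-um cutoff for real tubules
    group: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        for v in (self.motile_per_cell_mean, self.immotile_per_cell_mean, self.puncta_per_cell_mean):
            if v < 0:
                raise ValueError("per-cell means must be >= 0")
        if self.length_excess_mean <= 0:
            raise ValueError("length_excess_mean must be positive")


def simulate_tubule_tracks(config: TubuleSimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-cell tubule tracks; returns (tracks, true per-cell counts)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows = []
    true_counts = {}
    for c in range(cfg.n_cells):
        cell_id = f"{cfg.group}_c{c:03d}"
        n_motile = int(rng.poisson(cfg.motile_per_cell_mean))
        n_immotile = int(rng.poisson(cfg.immotile_per_cell_mean))
        n_puncta = int(rng.poisson(cfg.puncta_per_cell_mean))
        true_counts[cell_id] = n_motile
        t = 0
        for _ in range(n_motile):
            rows.append((cell_id, f"{cell_id}_t{t:03d}", 1.0 + rng.exponential(cfg.length_excess_mean), True))
            t += 1
        for _ in range(n_immotile):
            rows.append((cell_id, f"{cell_id}_t{t:03d}", 1.0 + rng.exponential(cfg.length_excess_mean), False))
            t += 1
        for _ in range(n_puncta):
            rows.append((cell_id, f"{cell_id}_t{t:03d}", rng.uniform(0.2, 0.95), True))
            t += 1
    tracks = pd.DataFrame(
        rows, columns=["cell_id", "tubule_id", "max_length_um", "moved_from_origin"]
    )
    counts = pd.Series(true_counts, name="n_motile_true")
    counts.index.name = "cell_id"
    return tracks, counts


# --------------------------------------------------------------------------
# writers (CLI `simulate` output)
# --------------------------------------------------------------------------


def write_proteome_sim(sim: ProteomeSim, out_dir) -> None:
    out = Path(out_dir)
    fio.write_table(sim.bait, out / "peptides_bait.tsv")
    fio.write_table(sim.control, out / "peptides_control.tsv")
    fio.write_table(sim.proteins, out / "proteins.tsv")
    fio.write_truth(
        {"true_interactors": sorted(sim.true_interactors), "config": asdict(sim.config)},
        out / "truth.json",
    )


def write_trace_sim(sim: TraceSim, out_dir) -> None:
    out = Path(out_dir)
    traces = sim.traces.copy()
    traces["channel2_present"] = traces["channel2_present"].astype(int)
    fio.write_table(traces, out / "traces.tsv")
    fio.write_table(sim.truth, out / "truth_events.tsv")
    movies = pd.DataFrame(
        {
            "movie_id": [f"m{m:03d}" for m in range(sim.config.n_movies)],
            "frame_interval_s": sim.config.frame_interval,
            "n_frames": sim.config.n_frames,
            "mt_length_um": sim.config.mt_length,
        }
    )
    fio.write_table(movies, out / "movies.tsv")
    fio.write_truth({"config": asdict(sim.config)}, out / "truth.json")


def write_roi_sim(rois: pd.DataFrame, out_dir, config: RoiSimConfig | None = None) -> None:
    out = Path(out_dir)
    fio.write_table(rois, out / "rois.tsv")
    if config is not None:
        fio.write_truth({"config": asdict(config)}, out / "truth.json")
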