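"""End-to-end orchestration: simulate -> segment -> regressors -> glm -> mtdnn.

A single config drives the whole run; every stage's seed is derived from a
base seed so reruns with the same config reproduce all artifacts
bit-identically.  Stage outputs land in a run directory together with a
manifest (config hash, per-stage seeds, artifact paths).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from . import synthetic
from .glm import (
    build_design_matrix,
    fit_subject_glm,
    group_ttest,
    network_overlap,
    permutation_cluster_correction,
)
from .microstates import (
    aahc_cluster,
    align_and_average_templates,
    assign_labels,
    bandpass_filter,
    compute_gfp,
    compute_similarity,
    detect_gfp_peaks,
    explained_variance,
    sample_peaks,
)
from .mtdnn import run_four_experiments
from .regressors import (
    build_censor_mask,
    build_regressor_set,
    finalize_regressor_set,
    hrf_double_gamma,
)
from .synthetic import BOLDDataset, SyntheticGroundTruth

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("mstate_bold")

STAGES = ("simulate", "segment", "regressors", "glm", "mtdnn")


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run.

    Defaults mirror the acquisition this pipeline targets: 32-channel EEG at
    250 Hz, TR = 2 s with 244 volumes, K = 4 microstates with ~50 ms dwell,
    a 2-20 Hz analysis band (1-40 Hz as the standard variant), a 2 s
    regressor window, and negative coupling of the activity regressors onto
    the sensory/attention blocks of a 7-network parcellation.
    """

    # geometry / acquisition
    n_subjects: int = 40
    n_channels: int = 32
    sfreq: float = 250.0
    tr: float = 2.0
    n_volumes: int = 244
    # microstates
    k: int = 4
    mean_dwell_ms: float = 50.0
    template_smoothness: float = 0.5
    band: tuple[float, float] = (2.0, 20.0)
    max_peaks: int = 10000
    # synthesis
    noise_sd: float = 0.2
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.3
    bold_noise_sd: float = 1.0
    coupling_beta: float = -0.5
    coupling_regressors: tuple[str, ...] = ("AT_A", "AT_B", "AT_C", "AT_D")
    coupled_networks: tuple[int, ...] = (1, 2, 3, 4)  # of the 7-network scheme
    n_networks: int = 7
    rois_per_network: int = 10
    motion_spikes: int = 2
    # regressors
    window_s: float = 2.0
    hrf: dict = field(
        default_factory=lambda: dict(
            peak_delay=6.0, undershoot_delay=16.0,
            peak_dispersion=1.0, undershoot_dispersion=1.0, ratio=6.0,
        )
    )
    censor_rms_threshold: float = 0.2
    # glm
    glm_regressor: str = "AT_A"
    voxel_p: float = 0.005
    cluster_p: float = 0.05
    n_perm: int = 10000
    # mtdnn
    neuron_grid: tuple[int, ...] = (5, 10, 20, 40)
    delay_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    grid_window: int = 30
    cv_initial: int = 31
    epochs: int = 100
    mtdnn_reg: float = 1e-2
    mtdnn_subjects: int | None = 1  # None = all (costly)
    # seeding
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.k < 1 or self.n_channels < self.k:
            raise ValueError("invalid geometry: need n_subjects>=1, n_channels>=k>=1")
        if not (0 < self.band[0] < self.band[1] < self.sfreq / 2):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.cv_initial < self.grid_window:
            raise ValueError("cv_initial must be >= grid_window")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("band", "coupling_regressors", "coupled_networks",
                    "neuron_grid", "delay_grid"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str, subject: int = 0) -> int:
        """Stable per-stage/per-subject sub-seed below 2**31."""
        h = hashlib.sha256(f"{self.seed}:{stage}:{subject}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def simulate_subject(
    config: PipelineConfig, templates: np.ndarray, subject: int
) -> tuple[SyntheticGroundTruth, "np.ndarray", BOLDDataset, np.ndarray]:
    """One subject's ground truth, EEG, BOLD, and motion traces.

    BOLD is mixed from the *ground-truth* finalized regressors (true labels
    and planted templates), so recovery by the analysis path is a genuine
    test rather than a tautology.
    """
    from .microstates import LabelSequence, MicrostateTemplateSet, microstate_names

    duration_s = config.n_volumes * config.tr
    seed = config.stage_seed("simulate", subject)
    tm = synthetic.uniform_transition_matrix(config.k)
    labels = synthetic.generate_state_sequence(
        tm, config.mean_dwell_ms, config.sfreq, duration_s, seed=seed
    )
    amplitude = synthetic.generate_amplitude(
        labels.n_samples, config.sfreq,
        mean=config.amplitude_mean, sd=config.amplitude_sd, seed=seed + 1,
    )
    parcellation = synthetic.seven_network_parcellation(
        config.n_networks, config.rois_per_network
    )
    n_rois = parcellation.size
    beta = np.zeros(n_rois)
    beta[np.isin(parcellation, config.coupled_networks)] = config.coupling_beta
    coupling = {name: beta for name in config.coupling_regressors}
    truth = SyntheticGroundTruth(
        templates=templates,
        state_sequence=labels.labels,
        amplitude=amplitude,
        noise_sd=config.noise_sd,
        transition_matrix=tm,
        mean_dwell_ms=config.mean_dwell_ms,
        coupling=coupling,
        bold_noise_sd=config.bold_noise_sd,
        seed=seed,
    )
    eeg = synthetic.generate_eeg(truth, sfreq=config.sfreq)
    # ground-truth regressors drive the BOLD mixture
    tset = MicrostateTemplateSet(
        templates=templates, labels=microstate_names(config.k), level="group"
    )
    true_labels = LabelSequence(labels=truth.state_sequence, sfreq=config.sfreq, k=config.k)
    regs = build_regressor_set(eeg, tset, labels=true_labels, window_s=config.window_s)
    hrf = hrf_double_gamma(dt=1.0 / config.sfreq, **config.hrf)
    regs = finalize_regressor_set(regs, config.tr, config.n_volumes, hrf=hrf)
    bold = synthetic.generate_bold(
        regs.tr_rate, coupling, config.bold_noise_sd, n_rois,
        seed=seed + 2, tr=config.tr, parcellation=parcellation,
    )
    motion = synthetic.generate_motion(
        config.n_volumes, seed=seed + 3, n_spikes=config.motion_spikes
    )
    return truth, eeg, bold, motion


def segment_subject(config: PipelineConfig, eeg, subject: int):
    """Band-pass, GFP peaks, subsample, AAHC -> one subject's template set."""
    filtered = bandpass_filter(eeg, *config.band)
    gfp = compute_gfp(filtered)
    peaks = detect_gfp_peaks(gfp, bad_intervals=eeg.bad_intervals)
    peaks = sample_peaks(
        peaks, config.max_peaks, seed=config.stage_seed("segment", subject)
    )
    return aahc_cluster(filtered.data[:, peaks].T, config.k), filtered


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: Path | str) -> dict:
    """Run all five stages; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": [],
        "seeds": {s: config.stage_seed(s) for s in STAGES},
        "artifacts": {},
    }
    config.to_yaml(out / "config.yaml")

    # -- simulate -----------------------------------------------------------
    logger.info("stage simulate: %d subjects", config.n_subjects)
    templates = synthetic.generate_templates(
        config.n_channels, config.k, config.template_smoothness,
        seed=config.stage_seed("simulate"),
    )
    subjects = []
    for s in range(config.n_subjects):
        truth, eeg, bold, motion = simulate_subject(config, templates, s)
        sdir = out / f"sub-{s:02d}"
        sdir.mkdir(exist_ok=True)
        mio.write_eeg(sdir / "eeg", eeg)
        mio.write_bold(sdir / "bold.tsv", bold)
        mio.write_motion(sdir / "motion.tsv", motion)
        mio.write_ground_truth(sdir / "truth.json", truth)
        subjects.append({"truth": truth, "eeg": eeg, "bold": bold, "motion": motion})
    manifest["stages"].append("simulate")

    # -- segment ------------------------------------------------------------
    logger.info("stage segment")
    subject_sets = []
    for s, sub in enumerate(subjects):
        tset, filtered = segment_subject(config, sub["eeg"], s)
        sub["filtered"] = filtered
        subject_sets.append(tset)
        mio.write_templates(out / f"sub-{s:02d}" / "templates.tsv", tset)
    group = align_and_average_templates(subject_sets)
    mio.write_templates(out / "group_templates.tsv", group)
    manifest["stages"].append("segment")
    manifest["artifacts"]["group_templates"] = "group_templates.tsv"

    # -- regressors ---------------------------------------------------------
    logger.info("stage regressors")
    hrf = hrf_double_gamma(dt=1.0 / config.sfreq, **config.hrf)
    gev_total = []
    for s, sub in enumerate(subjects):
        filtered = sub["filtered"]
        labels = assign_labels(compute_similarity(filtered, group), sfreq=config.sfreq)
        gev = explained_variance(filtered, group, labels)
        gev_total.append(gev["total"])
        regs = build_regressor_set(filtered, group, labels=labels, window_s=config.window_s)
        regs = finalize_regressor_set(
            regs, config.tr, config.n_volumes, hrf=hrf,
            motion=sub["motion"], eeg_bad_intervals=sub["eeg"].bad_intervals,
        )
        sub["labels"], sub["regs"], sub["gev"] = labels, regs, gev
        mio.write_labels(out / f"sub-{s:02d}" / "labels.tsv", labels)
        mio.write_regressors(out / f"sub-{s:02d}" / "regressors.tsv", regs)
    manifest["stages"].append("regressors")
    manifest["explained_variance_mean"] = float(np.mean(gev_total))

    # -- glm ----------------------------------------------------------------
    logger.info("stage glm: regressor %s", config.glm_regressor)
    betas = []
    usable_flags = []
    for sub in subjects:
        regs = sub["regs"]
        censored, usable = build_censor_mask(
            sub["motion"], sub["eeg"].bad_intervals, config.sfreq, config.tr,
            rms_threshold=config.censor_rms_threshold,
        )
        usable_flags.append(usable)
        if not usable:
            continue
        design = build_design_matrix(
            regs.tr_rate[config.glm_regressor], config.glm_regressor, motion=sub["motion"]
        )
        bold = sub["bold"]
        bold = BOLDDataset(
            data=bold.data, tr=bold.tr, censor=censored, parcellation=bold.parcellation
        )
        betas.append(fit_subject_glm(bold, design))
    betas = np.array(betas)
    result = group_ttest(betas)
    clusters = permutation_cluster_correction(
        result, betas,
        voxel_p=config.voxel_p, cluster_p=config.cluster_p,
        n_perm=config.n_perm, seed=config.stage_seed("glm"),
    )
    parcellation = subjects[0]["bold"].parcellation
    overlap = network_overlap(clusters, parcellation)
    mio.write_cluster_report(out / "clusters.tsv", clusters, overlap)
    manifest["stages"].append("glm")
    manifest["glm"] = {
        "n_usable_subjects": int(np.sum(usable_flags)),
        "mean_beta": float(np.mean(result.beta)),
        "n_significant_clusters": len(clusters.significant),
        "min_extent": clusters.min_extent,
    }

    # -- mtdnn --------------------------------------------------------------
    n_ml = config.mtdnn_subjects or config.n_subjects
    logger.info("stage mtdnn: %d subject(s)", n_ml)
    ml_rows = []
    for s, sub in enumerate(subjects[:n_ml]):
        regs = sub["regs"]
        dt = np.column_stack([regs.tr_rate[n] for n in regs.tr_rate if n.startswith("DT_")])
        dyn = np.column_stack(
            [regs.tr_rate[n] for n in regs.tr_rate if n.startswith(("AT_", "TS_"))]
        )
        bold_net = _network_average(sub["bold"])
        results = run_four_experiments(
            dt, dyn, bold_net,
            neuron_grid=config.neuron_grid, delay_grid=config.delay_grid,
            grid_window=config.grid_window, initial=config.cv_initial,
            reg=config.mtdnn_reg, seed=config.stage_seed("mtdnn", s),
            epochs=config.epochs, censor=regs.censor_mask,
        )
        for exp, res in results.items():
            ml_rows.append(
                {
                    "subject": s, "experiment": exp,
                    "r_h1": res.mean_r(1), "r_h2": res.mean_r(2),
                    "n_test_h1": res.n_test_h1, "n_test_h2": res.n_test_h2,
                    "n_hidden": res.n_hidden, "max_delay": res.max_delay,
                }
            )
    import pandas as pd

    ml_df = pd.DataFrame(ml_rows)
    ml_df.to_csv(out / "mtdnn_results.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["stages"].append("mtdnn")
    manifest["mtdnn"] = {
        row["experiment"]: {"r_h1": row["r_h1"], "r_h2": row["r_h2"]}
        for row in ml_rows
        if row["subject"] == 0
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _network_average(bold: BOLDDataset) -> np.ndarray:
    """TR x network mean BOLD series (the 7 outputs of the ML experiments)."""
    parc = bold.parcellation
    if parc is None:
        raise ValueError("BOLD dataset has no parcellation")
    nets = np.unique(parc[parc > 0])
    return np.column_stack([bold.data[parc == n].mean(axis=0) for n in nets])
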