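"""End-to-end study replica on synthetic cohorts.

``run_behavioral`` reproduces the behavioral chain: per-trial COP
generation -> 6 Hz low-pass -> sway metrics -> three-trial subject means
-> per-group paired Hotelling families (AP and ML sway triples) plus a
paired t on the ellipse area. ``run_connectome`` reproduces the EEG
chain: per-trial synthetic EEG -> preprocessing -> per-band, per-epoch
wPLI -> MST metrics averaged epochs -> trials -> subject -> per-metric
Hotelling across the three sub-bands with Simes post-hoc.

Seeding: every trial derives its generator from
``SeedSequence([master, group, subject, session, trial])`` while
subject-level baseline parameters derive from
``SeedSequence([master, group, subject])``, so pre and post share each
subject's baseline (the pairing the statistics rely on) and identical
configs give byte-identical outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import mst as mst_mod
from .config import StudyConfig
from .connectivity import connectivity_matrix
from .core import DataError, EegRecording
from .group_stats import PairedSample, hotelling_family, paired_t
from .posturography import SampEnConfig, lowpass_cop, sway_metrics
from .preprocessing import band_filter, preprocess
from .synthetic import CopSpec, CouplingSpec, gen_coupled_eeg, gen_cop

log = logging.getLogger("balancenet")

__all__ = [
    "run_behavioral",
    "run_connectome",
    "simulate_behavioral_cohort",
    "behavioral_stats",
    "connectome_stats",
]

_BEHAVIOR_FAMILIES = {
    "AP": ("rms_ap", "mf_ap", "sampen_ap"),
    "ML": ("rms_ml", "mf_ml", "sampen_ml"),
}
_TREE_METRICS = ("diameter", "leaf_fraction", "avg_eccentricity", "bc_max")


def _rng(master: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master), *key]))


def _group_index(cfg: StudyConfig, group: str) -> int:
    return sorted(cfg.groups).index(group)


def _subject_cop_baseline(cfg: StudyConfig, group: str, subject: int) -> dict:
    """Per-subject generative baseline, shared between sessions."""
    rng = _rng(cfg.seed, 11, _group_index(cfg, group), subject)
    base = np.asarray(cfg.cop_base_covariance, dtype=float)
    jitter = 1.0 + cfg.subject_cv * rng.standard_normal(2)
    jitter = np.clip(jitter, 0.3, None)
    cov = base * np.outer(jitter, jitter)  # keeps the matrix PSD
    centroid = cfg.cop_centroid_hz * float(
        np.clip(1.0 + cfg.subject_cv * rng.standard_normal(), 0.5, 1.5)
    )
    reg = float(np.clip(
        cfg.cop_regularity + 0.03 * rng.standard_normal(), 0.0, 0.9,
    ))
    return {"cov": cov, "centroid": centroid, "regularity": reg}


def _session_cop_spec(cfg: StudyConfig, base: dict, group: str,
                      subject: int, session: str) -> CopSpec:
    """Session-specific generative parameters for one subject.

    Day-to-day (session-level) variability perturbs every parameter so the
    paired statistics face realistic within-subject noise; the training
    effect is applied on top of the post session, to the AP axis only
    (the trained degree of freedom).
    """
    si = list(cfg.sessions).index(session)
    rng = _rng(cfg.seed, 13, _group_index(cfg, group), subject, si)
    cov = base["cov"].copy()
    scales = np.clip(1.0 + cfg.session_cv * rng.standard_normal(2), 0.3, None)
    cov *= np.outer(scales, scales)
    centroid = base["centroid"] * np.clip(
        1.0 + cfg.centroid_session_cv * rng.standard_normal(2), 0.4, 1.8,
    )
    # physiological floor: sway centroids below ~0.16 Hz are not realizable
    # together with the broadband correction component
    centroid = np.clip(centroid, 0.16, None)
    reg = np.clip(
        base["regularity"] + 0.05 * rng.standard_normal(2), 0.0, 0.9,
    )
    if session == "post":
        eff = cfg.behavior_effects.get(group, {})
        s = float(eff.get("ap_std_scale", 1.0))
        cov[0, 0] *= s * s
        cov[0, 1] *= s
        cov[1, 0] *= s
        centroid[0] *= float(eff.get("centroid_scale", 1.0))
        reg[0] = float(np.clip(
            reg[0] + eff.get("regularity_delta", 0.0), 0.0, 0.9,
        ))
    return CopSpec(
        duration_s=cfg.cop_duration_s, fs=cfg.cop_fs,
        covariance=tuple(map(tuple, cov)),
        spectral_centroid_hz=tuple(centroid), regularity=tuple(reg),
    )


def simulate_behavioral_cohort(cfg: StudyConfig) -> pd.DataFrame:
    """Generate and measure every COP trial of the synthetic cohort."""
    sampen_cfg = SampEnConfig(cfg.sampen_m, cfg.sampen_r_fraction,
                              cfg.sampen_target_fs)
    mf_kwargs = dict(
        window_s=cfg.welch_window_s, overlap_fraction=cfg.welch_overlap,
        band=cfg.mf_band, resolution_hz=cfg.welch_resolution_hz,
    )
    rows = []
    for group in sorted(cfg.groups):
        gi = _group_index(cfg, group)
        for subject in range(cfg.groups[group]):
            base = _subject_cop_baseline(cfg, group, subject)
            for si, session in enumerate(cfg.sessions):
                spec = _session_cop_spec(cfg, base, group, subject, session)
                for trial in range(cfg.n_trials):
                    seed_rng = _rng(cfg.seed, 12, gi, subject, si, trial)
                    trial_seed = int(seed_rng.integers(0, 2**31 - 1))
                    cop = gen_cop(spec, seed=trial_seed)
                    cop = lowpass_cop(cop, cfg.cop_lowpass_hz,
                                      cfg.cop_lowpass_order)
                    m = sway_metrics(cop, sampen_cfg, mf_kwargs)
                    rows.append({
                        "group": group, "subject": f"{group}{subject:02d}",
                        "session": session, "trial": trial, **m.as_dict(),
                    })
                log.info(
                    "behavioral %s subject %02d session %s: %d trials",
                    group, subject, session, cfg.n_trials,
                )
    return pd.DataFrame(rows)


def _subject_means(trials: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    return (
        trials.groupby(["group", "subject", "session"], as_index=False)
        [value_cols].mean()
    )


def _paired_matrices(sub: pd.DataFrame, cols: tuple[str, ...]
                     ) -> tuple[np.ndarray, np.ndarray]:
    pre = sub[sub.session == "pre"].sort_values("subject")
    post = sub[sub.session == "post"].sort_values("subject")
    if list(pre.subject) != list(post.subject):
        raise DataError("pre and post subject sets differ; pairing broken")
    if len(pre) < 2:
        raise DataError(
            "paired statistics require at least 2 subjects per group"
        )
    return pre[list(cols)].to_numpy(), post[list(cols)].to_numpy()


def behavioral_stats(trials: pd.DataFrame, alpha: float = 0.05
                     ) -> pd.DataFrame:
    """Group-level tests on the subject-mean sway metrics.

    Per group: Hotelling T2 on the (RMS, MF, SampEn) triple in each
    direction with Simes-controlled post-hoc t-tests, plus a paired t on
    CEA alone, mirroring the study's test layout.
    """
    value_cols = ["rms_ap", "rms_ml", "cea", "mf_ap", "mf_ml",
                  "sampen_ap", "sampen_ml"]
    means = _subject_means(trials, value_cols)
    rows = []
    for group, sub in means.groupby("group"):
        for family, cols in _BEHAVIOR_FAMILIES.items():
            pre, post = _paired_matrices(sub, cols)
            res = hotelling_family(
                PairedSample(pre, post, cols), alpha=alpha
            )
            rows.append({
                "group": group, "family": family, "variable": "",
                "statistic": res.statistic, "wilks_lambda": res.wilks_lambda,
                "df": str(res.df), "p": res.p_value,
                "simes_threshold": np.nan, "reject": res.p_value <= alpha,
            })
            for _, r in res.post_hoc.iterrows():
                rows.append({
                    "group": group, "family": family, "variable": r.variable,
                    "statistic": r.t, "wilks_lambda": np.nan, "df": "",
                    "p": r.p, "simes_threshold": r.simes_threshold,
                    "reject": bool(r.reject),
                })
        pre, post = _paired_matrices(sub, ("cea",))
        res = paired_t(pre[:, 0], post[:, 0])
        rows.append({
            "group": group, "family": "CEA", "variable": "cea",
            "statistic": res.statistic, "wilks_lambda": np.nan,
            "df": str(res.df), "p": res.p_value, "simes_threshold": np.nan,
            "reject": res.p_value <= alpha,
        })
    return pd.DataFrame(rows)


def run_behavioral(cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    trials = simulate_behavioral_cohort(cfg)
    return trials, behavioral_stats(trials, cfg.alpha)


# ------------------------------------------------------ connectome ----

def _topology_pairs(topology: str, n_channels: int
                    ) -> tuple[tuple[int, int], ...]:
    if topology == "path":
        return tuple((k, k + 1) for k in range(n_channels - 1))
    if topology == "hub":
        return tuple((0, j) for j in range(1, n_channels))
    raise DataError(f"unknown coupling topology {topology!r}")


def _gen_trial_eeg(cfg: StudyConfig, topology: str, strength: float,
                   seed: int) -> EegRecording:
    """Sum per-band coupled structures into one broadband recording."""
    from .preprocessing import BANDS

    rec = None
    for bi, band_label in enumerate(cfg.bands):
        spec = CouplingSpec(
            node_pairs=_topology_pairs(topology, cfg.eeg_n_channels),
            band=BANDS[band_label],
            phase_lag=cfg.coupling_phase_lag,
            coupling_strength=strength,
            snr_db=cfg.eeg_snr_db,
        )
        part = gen_coupled_eeg(
            spec, None, cfg.eeg_n_channels, cfg.eeg_fs,
            cfg.eeg_duration_s, seed=seed + bi,
            source_mode=(
                "shared-first-node" if topology == "hub" else "per-pair"
            ),
        )
        if rec is None:
            rec = part
        else:
            rec.data += part.data
    assert rec is not None
    # summed sub-band structures are rescaled to a typical 15 uV RMS scalp
    # amplitude so the +/-100 uV rejection threshold keeps clean epochs
    rec.data *= 15.0 / rec.data.std()
    if cfg.eeg_blink_rate_hz > 0:
        from .synthetic import gen_eog_artifacts

        gains = 0.5 * np.exp(-np.arange(cfg.eeg_n_channels) / 6.0)
        rec = gen_eog_artifacts(
            rec, cfg.eeg_blink_rate_hz, cfg.eeg_blink_amplitude_uv,
            gains, seed=seed + 101,
        ).contaminated
    return rec


def simulate_connectome_cohort(cfg: StudyConfig) -> pd.DataFrame:
    """Per-subject, per-band MST metrics from synthetic EEG cohorts."""
    rows = []
    for group in sorted(cfg.groups):
        gi = _group_index(cfg, group)
        for subject in range(cfg.groups[group]):
            subj_rng = _rng(cfg.seed, 21, gi, subject)
            strength_jitter = float(
                np.clip(1.0 + 0.1 * subj_rng.standard_normal(), 0.5, 1.4)
            )
            for si, session in enumerate(cfg.sessions):
                topology = cfg.coupling_topology[session][group]
                strength = float(np.clip(
                    cfg.coupling_strength[session][group] * strength_jitter,
                    0.0, 1.0,
                ))
                per_trial: dict[str, list] = {b: [] for b in cfg.bands}
                for trial in range(cfg.n_trials):
                    seed_rng = _rng(cfg.seed, 22, gi, subject, si, trial)
                    trial_seed = int(seed_rng.integers(0, 2**30))
                    rec = _gen_trial_eeg(cfg, topology, strength, trial_seed)
                    try:
                        eps = preprocess(
                            rec, None, cfg.epoch_length_s,
                            cfg.discard_head_s, cfg.amp_threshold_uv,
                            cfg.broadband,
                        )
                    except DataError as exc:
                        raise DataError(
                            f"{group} subject {subject} {session} trial "
                            f"{trial}: {exc}"
                        ) from exc
                    for band_label in cfg.bands:
                        beps = band_filter(eps, band_label)
                        cms = connectivity_matrix(
                            beps, "wPLI", cfg.wpli_variant
                        )
                        metrics = [
                            mst_mod.tree_metrics(
                                mst_mod.max_spanning_tree(cm),
                                cfg.mst_normalize,
                            )
                            for cm in cms
                        ]
                        per_trial[band_label].append(metrics)
                    log.info(
                        "connectome %s s%02d %s trial %d: %d/%d epochs kept",
                        group, subject, session, trial, eps.n_kept,
                        eps.n_epochs,
                    )
                for band_label in cfg.bands:
                    agg = mst_mod.aggregate_metrics(per_trial[band_label])
                    rows.append({
                        "group": group, "subject": f"{group}{subject:02d}",
                        "session": session, "band": band_label,
                        "n_trials": cfg.n_trials, **agg.as_dict(),
                    })
    return pd.DataFrame(rows)


def connectome_stats(metrics: pd.DataFrame, bands: tuple[str, ...],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-group, per-metric Hotelling across sub-bands + Simes post-hoc."""
    rows = []
    for group, sub in metrics.groupby("group"):
        for metric in _TREE_METRICS:
            wide = sub.pivot_table(
                index=["subject", "session"], columns="band", values=metric
            ).reset_index()
            cols = tuple(bands)
            pre, post = _paired_matrices(wide, cols)
            res = hotelling_family(PairedSample(pre, post, cols), alpha=alpha)
            rows.append({
                "group": group, "metric": metric, "band": "",
                "statistic": res.statistic, "wilks_lambda": res.wilks_lambda,
                "df": str(res.df), "p": res.p_value,
                "simes_threshold": np.nan, "reject": res.p_value <= alpha,
            })
            for _, r in res.post_hoc.iterrows():
                rows.append({
                    "group": group, "metric": metric, "band": r.variable,
                    "statistic": r.t, "wilks_lambda": np.nan, "df": "",
                    "p": r.p, "simes_threshold": r.simes_threshold,
                    "reject": bool(r.reject),
                })
    return pd.DataFrame(rows)


def run_connectome(cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    metrics = simulate_connectome_cohort(cfg)
    return metrics, connectome_stats(metrics, cfg.bands, cfg.alpha)
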