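"""The two-arm biomarker study as a model/results pair.

:class:`BiomarkerStudy` is constructed from a cohort of recordings (real
files or the synthetic generator) plus a :class:`StudyConfig`; ``fit()``
executes the full protocol — preprocessing, spectral and network feature
extraction, bootstrap mask discovery on the training split, group tests on
both splits, and the held-out QDA classification — and returns a
:class:`StudyResults` carrying the per-subject feature table, the masks,
every test with the name of the test used, the classifier metrics, and a
``summary()`` report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import networks as net
from .bootstrap import BootstrapConfig, bootstrap_edge_distributions, select_mask_edges
from .classify import (
    SubjectFeatures,
    classification_metrics,
    group_difference_test,
    qda_predict,
    qda_train,
)
from .preprocess import Recording, preprocess_recording
from .spectral import SpectralConfig, mean_spectrum, peak_alpha_ratio

logger = logging.getLogger(__name__)

MIN_CLEAN_SECONDS = 100.0


@dataclass
class StudyConfig:
    montage: str = "double_banana"
    state: str = "wake"
    q: float = 0.05                      # FDR level for epoch networks
    max_lag_ms: float = 500.0
    l_eff: float | None = None           # None -> connectivity default (100)
    n_boot: int = 2_000
    boot_seed: int = 0
    mask_mode: str = "union"
    group_test: str = "rank_sum"
    exclude_aspergers: bool = True
    qda_priors: str = "equal"
    alpha_band: tuple[float, float] = (8.0, 14.0)
    min_clean_seconds: float = MIN_CLEAN_SECONDS

    def spectral_config(self) -> SpectralConfig:
        return SpectralConfig(alpha_band=tuple(self.alpha_band))


def load_config(path) -> StudyConfig:
    """Load a YAML/JSON study configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    cfg = StudyConfig(**raw)
    for f, spec in StudyConfig.__dataclass_fields__.items():
        v = getattr(cfg, f)
        if f in ("l_eff",) and v is None:
            continue
        if spec.type in ("float", "float | None") and not isinstance(v, (int, float)):
            raise ValueError(f"{path}: key {f!r} must be numeric, got {type(v).__name__}")
    return cfg


@dataclass
class SubjectAnalysis:
    """Per-subject intermediates: epoch networks and the significance model."""

    features: SubjectFeatures
    networks: list
    model: conn.SignificanceModel
    n_epochs: int


def analyze_subject_networks(
    epoch_set, config: StudyConfig
) -> tuple[list[net.EpochNetwork], conn.SignificanceModel]:
    """Infer all epoch networks for one subject.

    A single pass over the epochs gathers the max/zero-lag statistics and
    fits the subject-level significance model (common variance plus the
    cross-epoch empirical edge null); each epoch is then FDR-thresholded.
    """
    sc = conn.subject_connectivity(
        epoch_set.epochs, epoch_set.fs, config.max_lag_ms, l_eff=config.l_eff
    )
    networks = [
        net.network_from_stats(*sc.edge_stats(e), sc.model, config.q)
        for e in range(epoch_set.n_epochs)
    ]
    return networks, sc.model


class BiomarkerStudy:
    """Two-arm EEG biomarker study model.

    Parameters
    ----------
    recordings : list of Recording
        The cohort; each recording carries its group label and
        training/validation split tag (the split is never re-randomized).
    config : StudyConfig
    """

    def __init__(self, recordings: list[Recording], config: StudyConfig | None = None):
        self.recordings = list(recordings)
        self.config = config or StudyConfig()
        self.truth = None   # optional CohortTruth for synthetic cohorts

    @classmethod
    def from_synthetic(cls, cohort_config=None, config: StudyConfig | None = None,
                       seed: int | None = None) -> "BiomarkerStudy":
        from .synthetic import CohortConfig, generate_cohort

        cc = cohort_config or CohortConfig()
        if seed is not None:
            cc = replace(cc, seed=seed)
        recordings, truth = generate_cohort(cc)
        study = cls(recordings, config)
        study.truth = truth
        return study

    @classmethod
    def from_directory(cls, path, config: StudyConfig | None = None) -> "BiomarkerStudy":
        from .io import read_cohort

        return cls(read_cohort(path), config)

    def fit(self) -> "StudyResults":
        cfg = self.config
        spectral_cfg = cfg.spectral_config()

        analyses: dict[str, SubjectAnalysis] = {}
        excluded: dict[str, str] = {}
        for rec in self.recordings:
            clean = rec.clean_seconds()
            if clean < cfg.min_clean_seconds:
                reason = (f"only {clean:.1f} s of artifact-free data "
                          f"(< {cfg.min_clean_seconds:.0f} s required)")
                excluded[rec.subject_id] = reason
                logger.warning("excluding %s: %s", rec.subject_id, reason)
                continue
            spec_epochs = preprocess_recording(rec, "spectral", cfg.montage, cfg.state)
            netw_epochs = preprocess_recording(rec, "network", cfg.montage, cfg.state)
            spectrum = mean_spectrum(spec_epochs, spectral_cfg)
            networks, model = analyze_subject_networks(netw_epochs, cfg)
            feats = SubjectFeatures(
                subject_id=rec.subject_id,
                group=rec.group_label,
                subtype=rec.subtype,
                split=rec.split,
                peak_alpha_ratio=peak_alpha_ratio(spectrum, spectral_cfg),
                mean_density=float(np.mean([net.density(n) for n in networks])),
            )
            analyses[rec.subject_id] = SubjectAnalysis(
                features=feats, networks=networks, model=model,
                n_epochs=netw_epochs.n_epochs,
            )

        if not analyses:
            raise ValueError("no subjects survived the inclusion criteria")

        # bootstrap mask on the training split
        training = {sid: a for sid, a in analyses.items()
                    if a.features.split == "training"}
        groups = {sid: a.features.group for sid, a in training.items()}
        templates = {
            sid: net.template_network(a.networks, "subject")
            for sid, a in training.items()
        }
        boot_cfg = BootstrapConfig(n_reps=cfg.n_boot, seed=cfg.boot_seed)
        dists = bootstrap_edge_distributions(
            {sid: training[sid].networks for sid in training}, groups, boot_cfg
        )
        obs_asd = net.template_network(
            [templates[s] for s in training if groups[s] == "ASD"], "group")
        obs_ctrl = net.template_network(
            [templates[s] for s in training if groups[s] == "control"], "group")
        mask = select_mask_edges(obs_asd, obs_ctrl, dists, boot_cfg, cfg.mask_mode)
        intersection = select_mask_edges(obs_asd, obs_ctrl, dists, boot_cfg,
                                         "intersection")

        for a in analyses.values():
            if len(mask):
                a.features.mask_density = net.subject_mask_density(a.networks, mask)
            if len(intersection):
                a.features.intersection_mask_density = net.subject_mask_density(
                    a.networks, intersection)

        features = pd.DataFrame([asdict(a.features) for a in analyses.values()])
        tests = self._group_tests(features)
        classifier = self._classify(features)

        return StudyResults(
            model=self,
            features=features,
            masks={"mask": mask, "intersection": intersection},
            group_templates={"ASD": obs_asd, "control": obs_ctrl},
            tests=tests,
            classifier=classifier,
            excluded=excluded,
            config=cfg,
        )

    def _group_tests(self, features: pd.DataFrame) -> dict:
        cfg = self.config
        out = {}
        measures = ["peak_alpha_ratio", "mean_density", "mask_density",
                    "intersection_mask_density"]
        for split in ("training", "validation"):
            sub = features[features.split == split]
            if sub.empty:
                continue
            asd = sub[sub.group == "ASD"]
            ctrl = sub[sub.group == "control"]
            if len(asd) < 2 or len(ctrl) < 2:
                continue
            # exploratory contrasts are two-sided; validation contrasts test
            # the directional hypotheses (ASD lower) formed on the training set
            alternative = "two_sided" if split == "training" else "A_less"
            for m in measures:
                a, c = asd[m].dropna(), ctrl[m].dropna()
                if len(a) < 2 or len(c) < 2:
                    continue
                p, name = group_difference_test(a, c, cfg.group_test, alternative)
                out[f"{split}:{m}"] = {"p": p, "test": name,
                                       "asd_mean": float(a.mean()),
                                       "control_mean": float(c.mean())}
        return out

    def _classify(self, features: pd.DataFrame) -> dict | None:
        cfg = self.config
        cols = ["peak_alpha_ratio", "mask_density"]
        df = features.dropna(subset=cols)
        if cfg.exclude_aspergers:
            df = df[df.subtype != "aspergers"]
        train = df[df.split == "training"]
        test = df[df.split == "validation"]
        if train.empty or test.empty:
            return None
        if min((train.group == "ASD").sum(), (train.group == "control").sum()) < 2:
            return None
        model = qda_train(train[cols].to_numpy(), train.group.to_numpy(),
                          priors=cfg.qda_priors, feature_names=tuple(cols))
        pred = qda_predict(model, test[cols].to_numpy())
        metrics = classification_metrics(pred, test.group.to_numpy())
        return {"model": model, "metrics": metrics,
                "features": tuple(cols), "priors": cfg.qda_priors,
                "n_train": len(train), "n_test": len(test)}


@dataclass
class StudyResults:
    """Fitted study: features, masks, tests, classifier, diagnostics."""

    model: BiomarkerStudy
    features: pd.DataFrame
    masks: dict
    group_templates: dict
    tests: dict
    classifier: dict | None
    excluded: dict
    config: StudyConfig

    def summary(self) -> str:
        lines = ["EEG biomarker study", "=" * 60]
        for split in ("training", "validation"):
            sub = self.features[self.features.split == split]
            if sub.empty:
                continue
            n_asd = (sub.group == "ASD").sum()
            n_ctrl = (sub.group == "control").sum()
            lines.append(f"{split}: {n_asd} ASD / {n_ctrl} control")
        if self.excluded:
            for sid, why in self.excluded.items():
                lines.append(f"excluded {sid}: {why}")
        mask = self.masks.get("mask")
        if mask is not None:
            lines.append(f"edge mask ({mask.provenance}): {len(mask)} edges")
        inter = self.masks.get("intersection")
        if inter is not None:
            lines.append(f"intersection mask: {len(inter)} edges")
        lines.append("-" * 60)
        lines.append(f"{'contrast':38s} {'ASD':>8s} {'control':>8s} {'p':>9s}")
        for key, t in self.tests.items():
            lines.append(
                f"{key:38s} {t['asd_mean']:8.3f} {t['control_mean']:8.3f} "
                f"{t['p']:9.4f}"
            )
        if self.classifier:
            m = self.classifier["metrics"]
            sens, spec = m.rounded_percent()
            lines.append("-" * 60)
            lines.append(
                f"QDA ({', '.join(self.classifier['features'])}; "
                f"priors={self.classifier['priors']}): "
                f"sensitivity {sens}% ({m.tp}/{m.tp + m.fn}), "
                f"specificity {spec}% ({m.tn}/{m.tn + m.fp})"
            )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Persist the feature table, masks, and a JSON report."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(out / "features.tsv", sep="\t", index=False)
        for name, mask in self.masks.items():
            if len(mask):
                mask.to_file(out / f"{name}_edges.txt")
        report = {
            "config": asdict(self.config),
            "tests": self.tests,
            "excluded": self.excluded,
        }
        if self.classifier:
            m = self.classifier["metrics"]
            report["classifier"] = {
                "features": list(self.classifier["features"]),
                "priors": self.classifier["priors"],
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "confusion": {"tp": m.tp, "fn": m.fn, "tn": m.tn, "fp": m.fp},
            }
        (out / "report.json").write_text(json.dumps(report, indent=1))
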