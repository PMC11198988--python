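"""End-to-end orchestration: simulate -> covariances -> centering -> manifolds
-> eccentricity -> contrasts -> behavior -> network inference.

Each stage reads its inputs from and writes its outputs to a single run
directory as TSV tables, so any prefix of the pipeline is resumable and every
intermediate is inspectable. A JSON manifest records the config echo, stage
timings, and a content hash of every produced file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .behavior import LearningCurve, bin_scores, learning_scores
from .inference import network_behavior_test, paired_contrast
from .io import RunConfig, ValidationError
from .manifold import align, build_affinity, build_template, embed
from .spd import CovarianceMatrix, CovarianceSet, center_set, shrinkage_covariance
from .synth import SyntheticStudyConfig, make_study, write_fixtures

logger = logging.getLogger("connmanifold")

EPOCHS = ["baseline", "early", "late"]

STAGES = [
    "simulate",
    "preprocess",
    "covary",
    "center",
    "manifold",
    "eccentricity",
    "contrast",
    "behavior",
    "infer",
]

#: files each stage needs before it can run
_REQUIRES = {
    "simulate": [],
    "preprocess": [],
    "covary": ["parcellation.tsv"],
    "center": ["covariances"],
    "manifold": ["centered"],
    "eccentricity": ["embeddings"],
    "contrast": ["eccentricity.tsv"],
    "behavior": ["trial_scores.tsv"],
    "infer": ["eccentricity.tsv", "learning_scores.tsv", "parcellation.tsv"],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _check_requires(out: Path, stage: str) -> None:
    for req in _REQUIRES[stage]:
        if not (out / req).exists():
            raise ValidationError(
                f"stage {stage!r} requires {req!r} in {out}; run the producing stage first"
            )


def _subjects(out: Path) -> list[str]:
    subs = sorted({p.name.split("_")[0] for p in (out / "covariances").glob("*.tsv")})
    if not subs:
        raise ValidationError("no covariance files found")
    return subs


class Pipeline:
    """Stage runner bound to one run directory and one configuration."""

    def __init__(self, config: RunConfig, out_dir: str | Path):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": config.to_dict(),
            "stages": [],
            "files": {},
            "warnings": [],
        }

    # -- stages ------------------------------------------------------------

    def simulate(self) -> None:
        syn = dict(self.config.synthetic)
        syn.setdefault("seed", self.config.seed)
        cfg = SyntheticStudyConfig(**syn)
        study = make_study(cfg)
        write_fixtures(study, self.out)
        np.savetxt(self.out / "truth_mask.tsv", study.affected_mask.astype(int), fmt="%d")
        np.savetxt(self.out / "truth_aptitude.tsv", study.aptitude, fmt=cio.FLOAT_FMT)

    def preprocess(self) -> None:
        """Denoise and epoch-split raw scans, if any are present.

        Consumes ``sub*_baseline_scan.tsv`` / ``sub*_learning_scan.tsv``
        (with optional ``sub*_confounds.tsv``) and emits the per-epoch
        ``sub*_{epoch}_timeseries.tsv`` files the covariance stage reads.
        Synthetic fixtures are generated already split, so the stage is a
        no-op when no raw scans exist.
        """
        from .preprocess import ConfoundSet, EpochSpec, denoise, split_epochs

        scans = sorted(self.out.glob("sub*_baseline_scan.tsv"))
        if not scans:
            logger.info("preprocess: no raw scans found; nothing to do")
            return
        spec = EpochSpec(
            discard_leading=self.config.discard_leading,
            epoch_length=self.config.epoch_length,
        )
        for baseline_path in scans:
            sub = baseline_path.name.split("_")[0]
            learning_path = self.out / f"{sub}_learning_scan.tsv"
            if not learning_path.exists():
                raise ValidationError(f"{sub}: baseline scan without learning scan")
            processed = []
            for path in (baseline_path, learning_path):
                ts = cio.read_timeseries(path)
                conf_path = self.out / f"{sub}_confounds.tsv"
                confounds = None
                if conf_path.exists():
                    vals, names = cio.read_matrix(conf_path)
                    confounds = ConfoundSet(vals, names)
                processed.append(
                    denoise(ts, confounds, self.config.highpass_s, self.config.lowpass_s)
                )
            for epoch, ts in zip(EPOCHS, split_epochs(processed[0], processed[1], spec)):
                cio.write_timeseries(ts, self.out / f"{sub}_{epoch}_timeseries.tsv")

    def covary(self) -> None:
        _check_requires(self.out, "covary")
        cov_dir = self.out / "covariances"
        cov_dir.mkdir(exist_ok=True)
        ts_files = sorted(self.out.glob("sub*_timeseries.tsv"))
        if not ts_files:
            raise ValidationError(f"no time-series files in {self.out}")
        for f in ts_files:
            ts = cio.read_timeseries(f)
            # z-score rows; synthetic series need no confound regression
            v = ts.values
            ts.values = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
            cov = shrinkage_covariance(ts)
            name = f.name.replace("_timeseries", "_cov")
            cio.write_matrix(cov.values, cov.region_ids, cov_dir / name)

    def center(self) -> None:
        _check_requires(self.out, "center")
        cov_dir = self.out / "covariances"
        cen_dir = self.out / "centered"
        cen_dir.mkdir(exist_ok=True)
        subjects = _subjects(self.out)
        grid = []
        for sub in subjects:
            row = []
            for epoch in EPOCHS:
                vals, ids = cio.read_matrix(cov_dir / f"{sub}_{epoch}_cov.tsv")
                row.append(CovarianceMatrix(values=vals, region_ids=ids))
            grid.append(row)
        cs = center_set(
            CovarianceSet(matrices=grid),
            tol=self.config.centering_tol,
            max_iter=self.config.centering_max_iter,
        )
        ids = cs.region_ids
        for i, sub in enumerate(subjects):
            for j, epoch in enumerate(EPOCHS):
                cio.write_matrix(cs.centered[i][j].values, ids, cen_dir / f"{sub}_{epoch}_cov.tsv")
        cio.write_matrix(cs.grand_mean, ids, self.out / "grand_mean_cov.tsv")

    def manifold(self) -> None:
        _check_requires(self.out, "manifold")
        cen_dir = self.out / "centered"
        emb_dir = self.out / "embeddings"
        emb_dir.mkdir(exist_ok=True)
        subjects = _subjects(self.out)
        d = self.config.manifold_dim
        frac = self.config.threshold_fraction
        baseline = []
        for sub in subjects:
            vals, ids = cio.read_matrix(cen_dir / f"{sub}_baseline_cov.tsv")
            baseline.append(CovarianceMatrix(values=vals, region_ids=ids))
        template = build_template(
            baseline, top_fraction=frac, d=d,
            tol=self.config.centering_tol, max_iter=self.config.centering_max_iter,
        )
        cols = [f"PC{c + 1}" for c in range(d)]
        cio.write_matrix(template.coords, cols, emb_dir / "template.tsv")
        self.manifest.setdefault("template_explained_variance", template.explained_variance.tolist())
        corrs = []
        for sub in subjects:
            for epoch in EPOCHS:
                vals, ids = cio.read_matrix(cen_dir / f"{sub}_{epoch}_cov.tsv")
                emb = embed(build_affinity(vals, frac, region_ids=ids), d)
                aligned = align(emb, template)
                corrs.append(np.nanmean(aligned.component_correlations))
                cio.write_matrix(aligned.coords, cols, emb_dir / f"{sub}_{epoch}.tsv")
        self.manifest["mean_alignment_correlation"] = float(np.nanmean(corrs))

    def eccentricity(self) -> None:
        _check_requires(self.out, "eccentricity")
        emb_dir = self.out / "embeddings"
        subjects = _subjects(self.out)
        meta = cio.read_parcellation(self.out / "parcellation.tsv")
        rows = []
        for sub in subjects:
            for epoch in EPOCHS:
                coords, _ = cio.read_matrix(emb_dir / f"{sub}_{epoch}.tsv")
                ecc = np.linalg.norm(coords, axis=1)
                rows.append(
                    pd.DataFrame(
                        {"region_id": meta.region_ids, "subject": sub, "epoch": epoch, "eccentricity": ecc}
                    )
                )
        df = pd.concat(rows, ignore_index=True)
        df.to_csv(self.out / "eccentricity.tsv", sep="\t", index=False, float_format=cio.FLOAT_FMT)

    def _ecc_matrix(self, epoch: str) -> tuple[np.ndarray, list[str], list[str]]:
        df = pd.read_csv(self.out / "eccentricity.tsv", sep="\t")
        sub = df[df.epoch == epoch].pivot(index="subject", columns="region_id", values="eccentricity")
        meta = cio.read_parcellation(self.out / "parcellation.tsv")
        sub = sub[meta.region_ids]  # restore region order
        return sub.to_numpy(), list(sub.index), meta.region_ids

    def contrast(self) -> None:
        _check_requires(self.out, "contrast")
        for a, b in (("baseline", "early"), ("early", "late")):
            MA, _, ids = self._ecc_matrix(a)
            MB, _, _ = self._ecc_matrix(b)
            cmap = paired_contrast(MA, MB, q=self.config.q, label=f"{b}>{a}", region_ids=ids)
            cmap.to_frame().to_csv(
                self.out / f"contrast_{b}_gt_{a}.tsv", sep="\t", index=False,
                float_format=cio.FLOAT_FMT,
            )

    def behavior(self) -> None:
        _check_requires(self.out, "behavior")
        df = pd.read_csv(self.out / "trial_scores.tsv", sep="\t")
        subjects = [c for c in df.columns if c != "trial"]
        curves = [LearningCurve(values=bin_scores(df[s].to_numpy()), subject=s) for s in subjects]
        scores, diag = learning_scores(curves)
        out = pd.DataFrame(
            {
                "subject": [s.subject for s in scores],
                "learning_score": [s.score for s in scores],
                "variance_explained": [s.variance_explained for s in scores],
            }
        )
        out.to_csv(self.out / "learning_scores.tsv", sep="\t", index=False, float_format=cio.FLOAT_FMT)
        self.manifest["fpca_penalty"] = diag["penalty"]

    def infer(self) -> None:
        _check_requires(self.out, "infer")
        meta = cio.read_parcellation(self.out / "parcellation.tsv")
        scores_df = pd.read_csv(self.out / "learning_scores.tsv", sep="\t")
        for a, b in (("baseline", "early"), ("early", "late")):
            MA, subs, _ = self._ecc_matrix(a)
            MB, _, _ = self._ecc_matrix(b)
            scores = scores_df.set_index("subject").loc[subs, "learning_score"].to_numpy()
            table = network_behavior_test(
                MB - MA,
                scores,
                meta,
                n_spins=self.config.n_spins,
                seed=self.config.seed + 17,
                q=self.config.q,
            )
            table.to_csv(
                self.out / f"network_behavior_{b}_gt_{a}.tsv", sep="\t", index=False,
                float_format=cio.FLOAT_FMT,
            )

    # -- driver ------------------------------------------------------------

    def run_stage(self, stage: str) -> None:
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}; choose from {STAGES}")
        t0 = time.perf_counter()
        getattr(self, stage)()
        elapsed = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", stage, elapsed)
        self.manifest["stages"].append({"stage": stage, "seconds": round(elapsed, 3)})

    def run(self, stages: list[str] | None = None) -> dict:
        for stage in stages or STAGES:
            self.run_stage(stage)
        self.finalize()
        return self.manifest

    def finalize(self) -> Path:
        for p in sorted(self.out.rglob("*.tsv")):
            self.manifest["files"][str(p.relative_to(self.out))] = _sha256(p)
        manifest_path = self.out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return manifest_path


def run(config: RunConfig, out_dir: str | Path, stages: list[str] | None = None) -> dict:
    """Run the full pipeline (or a list of stages) and return the manifest."""
    return Pipeline(config, out_dir).run(stages)
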