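"""Synthetic dataset generator.

Emulates the input contract of the evaluation pipeline on a small,
controllable scale: a log2-intensity feature-by-sample table with
co-expression modules, an optional batch shift, class-separating features,
MCAR missing values and pooled-reference QC replicates; module membership
doubles as complex and pathway annotation; a paired table is the main table
plus independent noise.

Generative model (all on the log2 scale)
----------------------------------------
Each feature f has a baseline ``b_f ~ N(baseline_mean, baseline_sd²)``.
Module features add a per-module, per-sample latent factor
``z_{m,s} ~ N(0, module_latent_sd²)`` plus i.i.d. noise
``N(0, noise_sd²)``; the population intra-module Pearson correlation is
therefore ``module_latent_sd² / (module_latent_sd² + noise_sd²)``.
Background features are i.i.d. with matching total variance and occupy the
leading rows; modules fill the trailing rows, so the class-separating
features (the first 20 rows) are background features whose class signal is
orthogonal to the module latents.  Samples in a
non-reference batch are shifted by ``batch_shift`` log2 units on every
feature.  One class level receives ``class_effect_sd`` on the first 20
features.  QC replicates are copies of the per-feature baseline plus
``qc_noise_sd`` noise and carry their own class label ``"QC"``.

Everything is reproducible from ``seed``: the same spec yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GeneSetCollection,
    GeneSetKind,
    OmicsDataTable,
    SampleAnnotation,
    Scale,
    ValidationError,
)
from . import io as qcio

N_CLASS_FEATURES = 20  # class effect goes on the first 20 features


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_features: int = 300
    n_samples: int = 40
    n_batches: int = 2
    batch_shift: float = 0.0  # log2 units added to non-reference batches
    n_modules: int = 4
    module_size: int = 20
    module_latent_sd: float = 1.0
    noise_sd: float = 0.5
    missing_rate: float = 0.05
    n_qc: int = 4
    qc_noise_sd: float = 0.2
    class_effect_sd: float = 2.0
    paired_noise_sd: float = 1.0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_features:
            raise ValidationError("n_modules * module_size must be <= n_features")
        for name in ("module_latent_sd", "noise_sd", "qc_noise_sd", "paired_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.n_samples < 4 or self.n_features < 1:
            raise ValidationError("need n_samples >= 4 and n_features >= 1")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")

    def intra_module_correlation(self) -> float:
        """Population Pearson r between two features of the same module."""
        v = self.module_latent_sd**2
        return v / (v + self.noise_sd**2)


@dataclass
class FixtureDataset:
    """In-memory synthetic dataset (one table plus side inputs)."""

    table: OmicsDataTable
    annotation: SampleAnnotation
    complexes: GeneSetCollection
    pathways: GeneSetCollection
    paired: OmicsDataTable
    spec: FixtureSpec


def _feature_ids(n: int) -> list[str]:
    return [f"F{i + 1:05d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def generate_dataset(spec: FixtureSpec, name: str = "T1") -> FixtureDataset:
    """Draw one dataset from the generative model."""
    rng = np.random.default_rng(spec.seed)
    n_f, n_s = spec.n_features, spec.n_samples
    features = _feature_ids(n_f)
    samples = _sample_ids(n_s)
    qc_samples = [f"QC{i + 1:02d}" for i in range(spec.n_qc)]

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_f)
    total_sd = float(np.hypot(spec.module_latent_sd, spec.noise_sd))

    # background features first, modules in the last rows: the
    # class-separating features (first rows) then carry independent noise,
    # keeping the class signal orthogonal to the module latents
    X = np.empty((n_f, n_s))
    n_mod_feats = spec.n_modules * spec.module_size
    mod_start = n_f - n_mod_feats
    for m in range(spec.n_modules):
        rows = slice(mod_start + m * spec.module_size,
                     mod_start + (m + 1) * spec.module_size)
        latent = rng.normal(0.0, spec.module_latent_sd, size=n_s)
        X[rows] = latent[None, :] + rng.normal(
            0.0, spec.noise_sd, size=(spec.module_size, n_s)
        )
    X[:mod_start] = rng.normal(0.0, total_sd, size=(mod_start, n_s))
    X += baseline[:, None]

    # annotation: class alternates with run order; batches are contiguous
    # blocks of the study samples, so batch and class are near-orthogonal
    classes = ["tumor" if i % 2 == 0 else "normal" for i in range(n_s)]
    batch_of = np.array(
        [min(i * spec.n_batches // n_s, spec.n_batches - 1) for i in range(n_s)]
    )
    batch_names = [f"B{b + 1}" for b in batch_of]

    X[:, batch_of > 0] += spec.batch_shift
    tumor_cols = np.array([c == "tumor" for c in classes])
    n_cls = min(N_CLASS_FEATURES, n_f)
    X[:n_cls, tumor_cols] += spec.class_effect_sd

    if spec.n_qc:
        qc_batches = [b % spec.n_batches for b in range(spec.n_qc)]
        Q = baseline[:, None] + rng.normal(0.0, spec.qc_noise_sd, size=(n_f, spec.n_qc))
        for j, b in enumerate(qc_batches):
            if b > 0:
                Q[:, j] += spec.batch_shift
        X = np.concatenate([X, Q], axis=1)

    all_samples = samples + qc_samples
    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X = X.copy()
        X[mask] = np.nan

    frame = pd.DataFrame(X, index=features, columns=all_samples)
    table = OmicsDataTable(name=name, values=frame, scale=Scale.LOG2)

    ann = pd.DataFrame(index=pd.Index(all_samples, name="sample"))
    ann["class_label"] = classes + ["QC"] * spec.n_qc
    ann["batch"] = batch_names + [f"B{(b % spec.n_batches) + 1}" for b in range(spec.n_qc)]
    ann["order"] = np.arange(1, len(all_samples) + 1, dtype=float)
    ann["is_qc"] = [False] * n_s + [True] * spec.n_qc
    annotation = SampleAnnotation(ann)

    module_sets = {
        f"M{m + 1:02d}": features[
            mod_start + m * spec.module_size : mod_start + (m + 1) * spec.module_size
        ]
        for m in range(spec.n_modules)
    }
    complexes = GeneSetCollection(GeneSetKind.COMPLEX, dict(module_sets))
    pathways = GeneSetCollection(GeneSetKind.PATHWAY, dict(module_sets))

    paired_frame = frame + rng.normal(0.0, spec.paired_noise_sd, size=frame.shape)
    paired = OmicsDataTable(name=f"{name}_paired", values=paired_frame, scale=Scale.LOG2)

    return FixtureDataset(
        table=table,
        annotation=annotation,
        complexes=complexes,
        pathways=pathways,
        paired=paired,
        spec=spec,
    )


def degrade_table(
    table: OmicsDataTable, noise_sd: float, seed: int, name: str | None = None
) -> OmicsDataTable:
    """Return a copy of *table* with i.i.d. Gaussian noise added.

    Missing entries stay missing.  Used to build matched clean/degraded
    table pairs for signal-ordering checks.
    """
    rng = np.random.default_rng(seed)
    noisy = table.values + rng.normal(0.0, noise_sd, size=table.values.shape)
    return OmicsDataTable(
        name=name or f"{table.name}_degraded", values=noisy, scale=table.scale
    )


def write_fixture(
    spec: FixtureSpec,
    out_dir: str | Path,
    degraded_noise_sd: float | None = None,
) -> dict[str, Path]:
    """Write a fixture dataset to disk in the pipeline's input formats.

    Emits ``tables/T1_clean.tsv`` (plus ``tables/T2_degraded.tsv`` when
    *degraded_noise_sd* is given), ``sample_annotation.tsv``,
    ``complexes.gmt``, ``pathways.gmt`` and ``paired.tsv``.  Returns the
    paths keyed by role.
    """
    out = Path(out_dir)
    tables_dir = out / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(spec, name="T1_clean")
    paths: dict[str, Path] = {}

    p = tables_dir / "T1_clean.tsv"
    qcio.write_data_table(ds.table, p)
    paths["table_clean"] = p
    if degraded_noise_sd is not None:
        noisy = degrade_table(
            ds.table, degraded_noise_sd, seed=spec.seed + 1, name="T2_degraded"
        )
        p = tables_dir / "T2_degraded.tsv"
        qcio.write_data_table(noisy, p)
        paths["table_degraded"] = p

    ann_path = out / "sample_annotation.tsv"
    with ann_path.open("w", encoding="utf-8") as fh:
        fh.write("sample\tclass\tbatch\torder\tis_qc\n")
        for sid, row in ds.annotation.table.iterrows():
            fh.write(
                f"{sid}\t{row['class_label']}\t{row['batch']}\t"
                f"{int(row['order'])}\t{int(bool(row['is_qc']))}\n"
            )
    paths["annotation"] = ann_path

    cpx_path = out / "complexes.gmt"
    qcio.write_gmt(ds.complexes, cpx_path)
    paths["complexes"] = cpx_path
    pw_path = out / "pathways.gmt"
    qcio.write_gmt(ds.pathways, pw_path)
    paths["pathways"] = pw_path

    paired_path = out / "paired.tsv"
    qcio.write_data_table(ds.paired, paired_path)
    paths["paired"] = paired_path
    return paths
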