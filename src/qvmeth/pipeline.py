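"""Glue joining I/O, feature extraction and the model into pipeline steps.

These helpers back the CLI commands and the reproduction script; they work
on in-memory objects so library users can call them directly.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx
import pysam

from . import io as qio
from .errors import (
    ContextUnencodableError,
    InsufficientDepthError,
    WindowOutOfBoundsError,
)
from .features import DEFAULT_LAYOUT, FeatureLayout, extract_features
from .model import MethylationLevelModel, TransformConfig
from .records import MethylationRecord
from .regions import range_trimmed_mean
from .simulate import SimulationConfig, simulate_dataset, split_train_test

logger = logging.getLogger(__name__)


@dataclass
class FeatureExtractionResult:
    """Feature matrix plus the loci that produced it and skip statistics."""

    X: np.ndarray
    loci: list[MethylationRecord]
    skipped: dict[str, int]
    layout: FeatureLayout

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "chrom": [r.chrom for r in self.loci],
            "start": [r.start for r in self.loci],
            "strand": [r.strand for r in self.loci],
            "depth": [r.depth for r in self.loci],
        }
        frame = pd.DataFrame(cols)
        feat = pd.DataFrame(
            self.X, columns=[f"f{i:05d}" for i in range(self.X.shape[1])]
        )
        return pd.concat([frame, feat], axis=1)


def extract_feature_matrix(
    bam: str | Path,
    fasta: str | Path,
    loci: list[MethylationRecord],
    flank: int = 10,
    min_depth: int = 10,
    flag_exclude: int = qio.DEFAULT_FLAG_EXCLUDE,
    deletion_qv: int = 0,
    sigma_ddof: int = 0,
) -> FeatureExtractionResult:
    """Window features for every workable locus in ``loci``.

    Loci are skipped (and counted) when their window crosses a contig edge,
    contains non-ACGT reference bases, or is covered by fewer than
    max(2, min_depth) eligible reads.
    """
    layout = FeatureLayout(flank=flank)
    fa = pyfaidx.Fasta(str(fasta))
    skipped = {"edge": 0, "context": 0, "depth": 0}
    rows: list[np.ndarray] = []
    kept: list[MethylationRecord] = []
    needed = max(2, min_depth)
    with pysam.AlignmentFile(str(bam)) as af:
        for rec in loci:
            try:
                context = qio.read_reference_window(
                    fa, rec.chrom, rec.start, flank
                )
            except WindowOutOfBoundsError:
                skipped["edge"] += 1
                continue
            except ContextUnencodableError:
                skipped["context"] += 1
                continue
            pileup = qio.collect_window_reads(
                af, rec.chrom, rec.start, flank=flank,
                flag_exclude=flag_exclude, deletion_qv=deletion_qv,
                context=context, strand=rec.strand,
            )
            if pileup.n < needed:
                skipped["depth"] += 1
                continue
            fv = extract_features(pileup, sigma_ddof=sigma_ddof, layout=layout)
            rows.append(fv.values)
            kept.append(
                MethylationRecord(
                    chrom=rec.chrom, start=rec.start, strand=rec.strand,
                    level=rec.level, depth=pileup.n, score=rec.score,
                )
            )
    X = (
        np.vstack(rows)
        if rows
        else np.empty((0, layout.total_length))
    )
    logger.info(
        "extracted features for %d loci (skipped: %s)", len(kept), skipped
    )
    return FeatureExtractionResult(X=X, loci=kept, skipped=skipped,
                                   layout=layout)


def write_feature_table(result: FeatureExtractionResult,
                        path: str | Path) -> None:
    """Write the feature table TSV with a layout header line."""
    with open(path, "w") as fh:
        fh.write(
            f"#layout_version={result.layout.version}\t"
            f"flank={result.layout.flank}\n"
        )
        result.to_frame().to_csv(fh, sep="\t", index=False,
                                 float_format="%.10g")


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, str, int]:
    """Read a feature table TSV; returns (frame, layout_version, flank)."""
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(
            part.split("=", 1) for part in header.lstrip("#").split("\t")
        )
        frame = pd.read_csv(fh, sep="\t")
    return frame, meta["layout_version"], int(meta["flank"])


def pearson(x, y) -> float:
    """Pearson correlation coefficient of two equally long vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def run_recovery_experiment(
    seed: int = 7,
    n_sites: int = 400,
    train_fraction: float = 0.75,
    coverage: int = 30,
    num_round: int = 200,
    families: tuple[str, ...] = ("mean", "cov", "coskew", "cokurt", "error"),
    region_block: int = 5,
    workdir: str | Path | None = None,
    nthread: int = 1,
) -> dict:
    """Simulate, train, and score held-out methylation recovery.

    Generates the default synthetic dataset (overriding site count, coverage
    and seed), extracts window features, trains the all-feature model plus
    one model per feature family on a train split, and reports held-out
    Pearson correlations between true and predicted methylation.  Test sites
    are additionally grouped into consecutive blocks of ``region_block``
    sites whose range-trimmed means give a region-level correlation.
    """
    own_tmp = workdir is None
    tmp = tempfile.TemporaryDirectory() if own_tmp else None
    workdir = Path(tmp.name) if own_tmp else Path(workdir)
    try:
        cfg = SimulationConfig(n_cpg=n_sites, coverage=coverage, seed=seed)
        data = simulate_dataset(cfg, workdir)
        bam = qio.sam_to_sorted_bam(data.sam, workdir / "reads.bam")
        loci = qio.read_loci_table(data.loci)
        result = extract_feature_matrix(bam, data.reference, loci)

        truth_by_pos = dict(
            zip(data.truth["position"], data.truth["true_level"])
        )
        true_levels = np.array([truth_by_pos[r.start] for r in result.loci])

        train_truth, test_truth = split_train_test(
            data.truth, train_fraction, seed
        )
        pos_index = {r.start: i for i, r in enumerate(result.loci)}
        train_idx = np.array(
            [pos_index[p] for p in train_truth["position"] if p in pos_index]
        )
        test_idx = np.array(
            [pos_index[p] for p in test_truth["position"] if p in pos_index]
        )

        labels = np.array([r.level for r in result.loci])
        out: dict = {
            "n_train": int(train_idx.size),
            "n_test": int(test_idx.size),
            "pcc": {},
        }
        y_true = true_levels[test_idx]
        for mask_name, mask in [("all", None)] + [
            (f, [f]) for f in families
        ]:
            model = MethylationLevelModel(
                result.X[train_idx], labels[train_idx],
                transform=TransformConfig(), feature_mask=mask,
            )
            fit = model.fit(num_round=num_round, seed=seed, nthread=nthread)
            if mask is None:
                X_test = result.X[test_idx]
            else:
                cols = result.layout.columns_for(mask)
                X_test = result.X[np.ix_(test_idx, cols)]
            pred = fit.trained.predict_levels(X_test)
            out["pcc"][mask_name] = pearson(y_true, pred)
            if mask is None:
                out["predicted_test_levels"] = pred
                out["true_test_levels"] = y_true

        pred = out["predicted_test_levels"]
        n_blocks = test_idx.size // region_block
        if n_blocks >= 2:
            block_pred = []
            block_true = []
            for b in range(n_blocks):
                sl = slice(b * region_block, (b + 1) * region_block)
                block_pred.append(range_trimmed_mean(pred[sl])[0])
                block_true.append(range_trimmed_mean(y_true[sl])[0])
            out["region_trimmed_mean_pcc"] = pearson(block_true, block_pred)
            out["n_regions"] = n_blocks
        return out
    finally:
        if own_tmp:
            tmp.cleanup()
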