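"""Synthetic aligned-read generator for end-to-end pipeline testing.

The simulator emulates the premise that 5mC perturbs basecall quality values
and sequencing errors near the methylated cytosine: a random reference with
planted CpG sites, per-site true methylation fractions drawn from a Beta
prior, and single-end reads whose per-read methylation state (Bernoulli at
the true fraction) additively shifts the QV mean and the substitution /
deletion probabilities at chosen offsets inside the ±``flank`` window.

Outputs are plain-text FASTA, coordinate-sorted SAM (with correct CIGARs —
deletions as D runs — and Phred+33 quality strings), a bedMethyl-dialect
loci table whose level is the realized methylated-read fraction, and a
truth table.  Everything is reproducible from the seed.

The defaults encode the reference simulation conditions used throughout the
test-suite: 400 CpG sites at coverage 30, Beta(0.3, 0.3) methylation prior,
a −6 Phred QV shift at offsets −2..+2 and substitution/deletion probability
shifts of +0.05/+0.03 at the site itself for methylated reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

_BASES = np.array(list("ACGT"))


def _default_qv_kernel() -> np.ndarray:
    k = np.zeros(21)
    k[8:13] = -6.0  # offsets -2..+2
    return k


def _default_sub_kernel() -> np.ndarray:
    k = np.zeros(21)
    k[10] = 0.05  # offset 0
    return k


def _default_del_kernel() -> np.ndarray:
    k = np.zeros(21)
    k[10] = 0.03  # offset 0
    return k


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; all offsets span −flank..+flank."""

    genome_length: int = 20000
    n_cpg: int = 400
    coverage: int = 30
    methylation_prior: tuple[float, float] = (0.3, 0.3)  # Beta(a, b)
    qv_baseline: tuple[float, float] = (20.0, 5.0)  # mean, sd (Phred)
    qv_shift_kernel: np.ndarray = field(default_factory=_default_qv_kernel)
    error_baseline: tuple[float, float] = (0.03, 0.02)  # substitution, deletion
    substitution_shift_kernel: np.ndarray = field(
        default_factory=_default_sub_kernel
    )
    deletion_shift_kernel: np.ndarray = field(default_factory=_default_del_kernel)
    flank: int = 10
    min_spacing: int = 25
    read_margin: tuple[int, int] = (5, 20)  # extra bases beyond the window
    chrom_name: str = "sim1"
    emit_reverse_records: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        width = 2 * self.flank + 1
        for name in ("qv_shift_kernel", "substitution_shift_kernel",
                     "deletion_shift_kernel"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (width,):
                raise ConfigError(
                    f"{name} must have length {width}, got {arr.shape}"
                )
            setattr(self, name, arr)
        if self.coverage < 1:
            raise ConfigError("coverage must be >= 1")
        sub, dele = self.error_baseline
        if not (0 <= sub <= 1 and 0 <= dele <= 1):
            raise ConfigError("error probabilities must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    """File paths plus the in-memory truth table of one simulated dataset."""

    reference: Path
    sam: Path
    loci: Path
    truth_path: Path
    truth: pd.DataFrame
    config: SimulationConfig


def _place_sites(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """CpG positions >= min_spacing apart and clear of the contig ends."""
    pad = max(cfg.min_spacing, cfg.flank + cfg.read_margin[1] + 2)
    usable = cfg.genome_length - 2 * pad
    slot = usable // cfg.n_cpg if cfg.n_cpg else 0
    if cfg.n_cpg < 1 or slot < cfg.min_spacing:
        raise ConfigError(
            f"cannot place {cfg.n_cpg} sites {cfg.min_spacing} bases apart "
            f"in a {cfg.genome_length}-base genome"
        )
    jitter_span = slot - cfg.min_spacing + 1
    jitter = rng.integers(0, jitter_span, size=cfg.n_cpg)
    return pad + np.arange(cfg.n_cpg) * slot + jitter


def _simulate_read(
    ref: np.ndarray,
    site: int,
    methylated: bool,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[int, str, str, str]:
    """One aligned read covering the site's window; returns
    (ref start, seq, qual string, CIGAR)."""
    lo, hi = cfg.read_margin
    ml = int(rng.integers(lo, hi + 1))
    mr = int(rng.integers(lo, hi + 1))
    start = site - cfg.flank - ml
    end = site + cfg.flank + 1 + mr
    span = end - start
    sub_base, del_base = cfg.error_baseline

    p_del = np.full(span, del_base)
    p_sub = np.full(span, sub_base)
    qv_mu = np.full(span, cfg.qv_baseline[0])
    if methylated:
        w0 = (site - cfg.flank) - start  # window start within the read span
        sl = slice(w0, w0 + 2 * cfg.flank + 1)
        p_del[sl] = np.clip(p_del[sl] + cfg.deletion_shift_kernel, 0, 1)
        p_sub[sl] = np.clip(p_sub[sl] + cfg.substitution_shift_kernel, 0, 1)
        qv_mu[sl] = qv_mu[sl] + cfg.qv_shift_kernel

    # deletions first, then substitutions on the surviving bases
    deleted = rng.random(span) < p_del
    substituted = (~deleted) & (rng.random(span) < p_sub)
    qvs = np.clip(
        np.rint(rng.normal(qv_mu, cfg.qv_baseline[1])), 1, 50
    ).astype(int)

    seq_chars: list[str] = []
    qual_chars: list[str] = []
    cigar_ops: list[str] = []
    run_op, run_len = "", 0
    for k in range(span):
        op = "D" if deleted[k] else "M"
        if op == run_op:
            run_len += 1
        else:
            if run_op:
                cigar_ops.append(f"{run_len}{run_op}")
            run_op, run_len = op, 1
        if deleted[k]:
            continue
        base = ref[start + k]
        if substituted[k]:
            others = [b for b in "ACGT" if b != base]
            base = others[int(rng.integers(0, 3))]
        seq_chars.append(base)
        qual_chars.append(chr(qvs[k] + 33))
    cigar_ops.append(f"{run_len}{run_op}")
    return start, "".join(seq_chars), "".join(qual_chars), "".join(cigar_ops)


def simulate_dataset(
    cfg: SimulationConfig, outdir: str | Path
) -> SimulatedDataset:
    """Generate the reference, reads, loci table and truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    ref = rng.choice(_BASES, size=cfg.genome_length)
    sites = _place_sites(cfg, rng)
    ref[sites] = "C"
    ref[sites + 1] = "G"

    a, b = cfg.methylation_prior
    true_levels = rng.beta(a, b, size=cfg.n_cpg)

    sam_records: list[tuple[int, str]] = []  # (ref start, full SAM line tail)
    meth_counts = np.zeros(cfg.n_cpg, dtype=int)
    for si, site in enumerate(sites):
        states = rng.random(cfg.coverage) < true_levels[si]
        meth_counts[si] = int(states.sum())
        for j in range(cfg.coverage):
            start, seq, qual, cigar = _simulate_read(
                ref, int(site), bool(states[j]), cfg, rng
            )
            qname = f"read_{si:05d}_{j:03d}"
            line = (
                f"{qname}\t0\t{cfg.chrom_name}\t{start + 1}\t60\t{cigar}\t"
                f"*\t0\t0\t{seq}\t{qual}"
            )
            sam_records.append((start, line))

    ref_path = outdir / "reference.fa"
    with open(ref_path, "w") as fh:
        fh.write(f">{cfg.chrom_name}\n")
        seq = "".join(ref)
        for i in range(0, len(seq), 70):
            fh.write(seq[i: i + 70] + "\n")

    sam_path = outdir / "reads.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{cfg.chrom_name}\tLN:{cfg.genome_length}\n")
        for _, line in sorted(sam_records, key=lambda t: t[0]):
            fh.write(line + "\n")

    loci_path = outdir / "loci.bed"
    with open(loci_path, "w") as fh:
        for si, site in enumerate(sites):
            pct = 100.0 * meth_counts[si] / cfg.coverage
            fh.write(
                f"{cfg.chrom_name}\t{site}\t{site + 1}\tCpG\t1000\t+\t"
                f"{site}\t{site + 1}\t0,0,0\t{cfg.coverage}\t{pct:.2f}\n"
            )
            if cfg.emit_reverse_records:
                fh.write(
                    f"{cfg.chrom_name}\t{site + 1}\t{site + 2}\tCpG\t1000\t-\t"
                    f"{site + 1}\t{site + 2}\t0,0,0\t{cfg.coverage}\t"
                    f"{pct:.2f}\n"
                )

    truth = pd.DataFrame(
        {
            "chrom": cfg.chrom_name,
            "position": sites,
            "strand": "+",
            "true_level": true_levels,
            "methylated_reads": meth_counts,
            "coverage": cfg.coverage,
        }
    )
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6f")

    return SimulatedDataset(
        reference=ref_path,
        sam=sam_path,
        loci=loci_path,
        truth_path=truth_path,
        truth=truth,
        config=cfg,
    )


def split_train_test(
    truth: pd.DataFrame, fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint train/test site split; ``fraction`` goes to training."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(truth))
    n_train = int(round(fraction * len(truth)))
    train = truth.iloc[np.sort(idx[:n_train])].reset_index(drop=True)
    test = truth.iloc[np.sort(idx[n_train:])].reset_index(drop=True)
    return train, test
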