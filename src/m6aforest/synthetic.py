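"""Self-contained synthetic fixtures with the signal structure the model assumes.

The generator emulates the phenomenology of fraction-modified tracks from
direct-RNA nanopore preprocessing: values hover around 0.5 everywhere (the
per-base deviation statistic is noisy even at unmodified positions), and
methylated DRACH sites add a spike at the bases immediately 5' of the motif.
A perturbed condition (writer knockdown / eraser overexpression) attenuates
the spike while redrawing the noise.  The truth BED deliberately labels only
a fraction of the truly methylated sites, mimicking antibody-based truth
sets that miss real sites; the manifest records complete ground truth.

Background sequence is scrubbed of accidental DRACH occurrences so every
candidate site the scanner finds is a planted one with known status.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from m6aforest.model import ConfigurationError
from m6aforest.motifs import _DRACH_RE
from m6aforest.signal_io import (
    CoverageTrack,
    SignalTrack,
    write_bedgraph,
    write_wiggle,
)

#: base to substitute at each motif offset to break a DRACH occurrence
_BREAKERS = "CCCAG"

MANIFEST_NAME = "manifest.tsv"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic data set.

    Defaults describe the baseline study conditions: fraction-modified noise
    centred at 0.5, a spike of +0.3 at the three bases 5' of methylated
    motifs, Gaussian noise sd 0.1, coverage uniform in [5, 50], 70% of the
    methylated sites annotated in the truth BED, and a perturbation that
    removes the spike entirely (attenuation 1.0; 0.0 gives a null
    perturbation that only redraws the noise).
    """

    n_sequences: int = 10
    seq_length: int = 3000
    n_methylated_sites: int = 500
    n_unmethylated_drach_decoys: int = 500
    baseline_mean: float = 0.5
    peak_delta: float = 0.3
    noise_sd: float = 0.1
    peak_offsets: tuple[int, ...] = (-5, -4, -3)
    coverage_min: int = 5
    coverage_max: int = 50
    truth_label_fraction: float = 0.7
    perturbation_attenuation: float = 1.0
    motifs: tuple[str, ...] = ("AGACT", "GGACA", "GGACC", "GGACT")
    flank: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_mean", "truth_label_fraction", "perturbation_attenuation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0 or self.peak_delta < 0:
            raise ValueError("noise_sd and peak_delta must be >= 0")
        if self.coverage_min > self.coverage_max:
            raise ValueError("coverage_min > coverage_max")


def _scrub_accidental_drach(
    seq: np.ndarray, planted_centers: set[int], protected: np.ndarray
) -> None:
    """Mutate bases in place until the only DRACH occurrences are planted ones.

    Any accidental occurrence shares at most 4 bases with a planted 5-mer,
    so at least one of its positions is mutable; substituting the breaker
    base at that offset invalidates the occurrence.
    """
    for _ in range(200):
        text = "".join(seq)
        accidental = [
            m.start() + 2
            for m in _DRACH_RE.finditer(text)
            if m.start() + 2 not in planted_centers
        ]
        if not accidental:
            return
        for center in accidental:
            for offset in range(5):
                idx = center - 2 + offset
                if not protected[idx]:
                    seq[idx] = _BREAKERS[offset]
                    break
    raise RuntimeError("DRACH scrubbing did not converge")  # pragma: no cover


def _plan_sites(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Choose non-overlapping planted positions and assign motif and status."""
    spacing = 2 * config.flank + 5
    margin = max(config.flank, 2)
    slots = [
        (f"seq{i:03d}", pos)
        for i in range(config.n_sequences)
        for pos in range(margin, config.seq_length - margin - 2, spacing)
    ]
    n_total = config.n_methylated_sites + config.n_unmethylated_drach_decoys
    if n_total > len(slots):
        raise ConfigurationError(
            f"requested {n_total} sites but only {len(slots)} placeable slots "
            f"(n_sequences={config.n_sequences}, seq_length={config.seq_length})"
        )
    chosen = [slots[i] for i in rng.permutation(len(slots))[:n_total]]
    motifs = rng.choice(config.motifs, size=n_total)
    status = ["methylated"] * config.n_methylated_sites + [
        "unmethylated"
    ] * config.n_unmethylated_drach_decoys
    df = pd.DataFrame(
        {
            "ref": [c[0] for c in chosen],
            "a_pos": [c[1] for c in chosen],
            "motif": motifs,
            "true_status": status,
        }
    )
    n_labeled = int(round(config.truth_label_fraction * config.n_methylated_sites))
    meth_idx = df.index[df["true_status"] == "methylated"].to_numpy()
    labeled_idx = set(rng.permutation(meth_idx)[:n_labeled].tolist())
    df["labeled_in_truth_bed"] = [i in labeled_idx for i in df.index]
    return df.sort_values(["ref", "a_pos"], ignore_index=True)


def generate_fixture(config: SyntheticConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a complete fixture into ``out_dir``; returns the site manifest.

    Files written: reference.fa, wt.wig / wt.bedgraph, perturbed.wig /
    perturbed.bedgraph, truth.bed, manifest.tsv and config.json.  Identical
    configs (same seed) produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = _plan_sites(config, rng)

    bases = np.array(list("ACGT"))
    wt_signal = SignalTrack()
    pert_signal = SignalTrack()
    wt_cov = CoverageTrack()
    pert_cov = CoverageTrack()
    sequences: dict[str, str] = {}

    for i in range(config.n_sequences):
        ref = f"seq{i:03d}"
        seq = bases[rng.integers(0, 4, config.seq_length)].copy()
        sites = manifest[manifest["ref"] == ref]
        protected = np.zeros(config.seq_length, dtype=bool)
        for _, row in sites.iterrows():
            a = int(row["a_pos"])
            seq[a - 2 : a + 3] = list(row["motif"])
            protected[a - 2 : a + 3] = True
        _scrub_accidental_drach(
            seq, set(sites["a_pos"].astype(int)), protected
        )
        sequences[ref] = "".join(seq)

        peak = np.zeros(config.seq_length)
        for _, row in sites.iterrows():
            if row["true_status"] != "methylated":
                continue
            for off in config.peak_offsets:
                peak[int(row["a_pos"]) + off] += config.peak_delta

        wt_vals = np.clip(
            config.baseline_mean
            + peak
            + rng.normal(0.0, config.noise_sd, config.seq_length),
            0.0,
            1.0,
        )
        pert_vals = np.clip(
            config.baseline_mean
            + peak * (1.0 - config.perturbation_attenuation)
            + rng.normal(0.0, config.noise_sd, config.seq_length),
            0.0,
            1.0,
        )
        wt_signal.values[ref] = {p: float(v) for p, v in enumerate(wt_vals)}
        pert_signal.values[ref] = {p: float(v) for p, v in enumerate(pert_vals)}
        wt_cov.counts[ref] = {
            p: int(c)
            for p, c in enumerate(
                rng.integers(config.coverage_min, config.coverage_max + 1, config.seq_length)
            )
        }
        pert_cov.counts[ref] = {
            p: int(c)
            for p, c in enumerate(
                rng.integers(config.coverage_min, config.coverage_max + 1, config.seq_length)
            )
        }

    with open(out / "reference.fa", "w") as fh:
        for ref in sorted(sequences):
            fh.write(f">{ref}\n")
            s = sequences[ref]
            for start in range(0, len(s), 60):
                fh.write(s[start : start + 60] + "\n")
    write_wiggle(wt_signal, out / "wt.wig")
    write_wiggle(pert_signal, out / "perturbed.wig")
    write_bedgraph(wt_cov, out / "wt.bedgraph")
    write_bedgraph(pert_cov, out / "perturbed.bedgraph")

    truth = manifest[manifest["labeled_in_truth_bed"]]
    with open(out / "truth.bed", "w") as fh:
        for _, row in truth.iterrows():
            a = int(row["a_pos"])
            fh.write(f"{row['ref']}\t{a}\t{a + 1}\tm6A\t0\t+\n")

    manifest.to_csv(out / MANIFEST_NAME, sep="\t", index=False)
    cfg = asdict(config)
    cfg["motifs"] = list(cfg["motifs"])
    cfg["peak_offsets"] = list(cfg["peak_offsets"])
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def manifest_truth(out_dir: str | Path) -> pd.DataFrame:
    """Load the per-site ground-truth table written by :func:`generate_fixture`."""
    path = Path(out_dir) / MANIFEST_NAME
    if not path.exists():
        raise FileNotFoundError(f"no fixture manifest at {path}")
    return pd.read_csv(path, sep="\t")
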