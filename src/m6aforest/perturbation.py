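"""Writer/eraser perturbation-sensitivity scoring.

Methylated sites show a spike in the fraction-modified signal at the bases
immediately 5' of the DRACH motif.  Depleting the m6A writer (METTL3) or
overexpressing the eraser (ALKBH5) lowers that spike, so a site is
*sensitive* when its mean signal over the peak positions is strictly greater
in the baseline condition than in the perturbed one.  Comparing the
sensitive fraction between predicted-m6A and predicted-unmethylated sites
validates calls without antibody-based truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from m6aforest.features import FeatureWindow
from m6aforest.predict import CALL_M6A, CALL_NOT, PredictionRecord

#: Offsets of the signal spike relative to the central A: the three bases
#: immediately 5' of the motif's first base (motif spans offsets -2..+2).
DEFAULT_PEAK_OFFSETS = (-5, -4, -3)


class PairingError(ValueError):
    """The two windows do not describe the same site."""


@dataclass(frozen=True)
class SensitivityResult:
    site: object
    wt_peak_mean: float
    perturbed_peak_mean: float
    sensitive: bool


def site_sensitivity(
    window_wt: FeatureWindow,
    window_perturbed: FeatureWindow,
    peaks: Sequence[int] = DEFAULT_PEAK_OFFSETS,
) -> SensitivityResult:
    """Score one site: sensitive iff wt peak mean strictly exceeds perturbed.

    Means are taken over exactly the ``peaks`` offsets (transcript-sense,
    relative to the central A).  Ties are not sensitive.
    """
    if window_wt.site.key != window_perturbed.site.key:
        raise PairingError(
            f"window pair describes different sites: "
            f"{window_wt.site.key} vs {window_perturbed.site.key}"
        )
    if window_wt.flank != window_perturbed.flank:
        raise PairingError("window pair has mismatched flanks")
    flank = window_wt.flank
    for off in peaks:
        if not -flank <= off <= flank:
            raise ValueError(f"peak offset {off} outside +/-{flank} window")
    wt_mean = sum(window_wt.value_at_offset(o) for o in peaks) / len(peaks)
    pert_mean = sum(window_perturbed.value_at_offset(o) for o in peaks) / len(peaks)
    return SensitivityResult(
        site=window_wt.site,
        wt_peak_mean=wt_mean,
        perturbed_peak_mean=pert_mean,
        sensitive=wt_mean > pert_mean,
    )


def pair_windows(
    wt_windows: Iterable[FeatureWindow],
    perturbed_windows: Iterable[FeatureWindow],
) -> tuple[list[tuple[FeatureWindow, FeatureWindow]], int]:
    """Match windows across conditions by site; returns (pairs, n_unpaired).

    Sites present in only one condition (e.g. dropped by the coverage filter
    there) cannot be scored and are counted as unpaired.
    """
    wt_by_key = {w.site.key: w for w in wt_windows}
    pert_by_key = {w.site.key: w for w in perturbed_windows}
    keys = sorted(set(wt_by_key) & set(pert_by_key))
    pairs = [(wt_by_key[k], pert_by_key[k]) for k in keys]
    unpaired = len(set(wt_by_key) ^ set(pert_by_key))
    return pairs, unpaired


@dataclass
class ClassFraction:
    n_sensitive: int
    n_total: int

    @property
    def fraction(self) -> float | None:
        """Sensitive fraction; None (undefined) for an empty class."""
        return self.n_sensitive / self.n_total if self.n_total else None


def sensitivity_fractions(
    pairs: Sequence[tuple[FeatureWindow, FeatureWindow]],
    predictions: Mapping[tuple, PredictionRecord] | Sequence[PredictionRecord],
    peaks: Sequence[int] = DEFAULT_PEAK_OFFSETS,
) -> dict[str, ClassFraction]:
    """Fraction of sensitive sites per prediction class (m6A / not_m6A).

    Every paired site must have a prediction; an empty class reports an
    undefined fraction (None) rather than 0.
    """
    if not isinstance(predictions, Mapping):
        predictions = {p.site.key: p for p in predictions}
    out = {CALL_M6A: ClassFraction(0, 0), CALL_NOT: ClassFraction(0, 0)}
    for wt, pert in pairs:
        key = wt.site.key
        if key not in predictions:
            raise KeyError(f"paired site without a prediction: {key}")
        result = site_sensitivity(wt, pert, peaks)
        cf = out[predictions[key].call]
        cf.n_total += 1
        cf.n_sensitive += int(result.sensitive)
    return out


def write_sensitivity_report(
    fractions: Mapping[str, ClassFraction],
    path,
    n_unpaired: int = 0,
) -> None:
    with open(path, "w") as fh:
        fh.write("class\tn_sensitive\tn_total\tfraction\n")
        for cls in sorted(fractions):
            cf = fractions[cls]
            frac = "NA" if cf.fraction is None else f"{cf.fraction:.4f}"
            fh.write(f"{cls}\t{cf.n_sensitive}\t{cf.n_total}\t{frac}\n")
        fh.write(f"#unpaired_sites\t{n_unpaired}\n")
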