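"""Global repeat map (GRM): fragment-length spectra and peak calling.

The GRM diagram of a sequence is the histogram of distances between
consecutive occurrences of every repeated k-mer key.  A tandem repeat with
unit length L contributes mass at L and its multiples, so peaks in the
spectrum reveal monomer and higher-order-repeat (HOR) periods: for
NBPF-like arrays, ~1.6 kb (monomer), ~3.2 kb (2mer) and ~4.8 kb (3mer
HOR / Olduvai triplet).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .seqio import GenomeSequence

DEFAULT_KEY_LENGTH = 8
# Window bracketing NBPF periods (monomer ~1.6 kb up to the 3mer ~4.8 kb).
DEFAULT_LENGTH_MIN = 1_000
DEFAULT_LENGTH_MAX = 6_000

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclass
class GRMSpectrum:
    """Fragment-length -> frequency histogram over [length_min, length_max]."""

    length_min: int
    length_max: int
    key_length: int
    counts: dict[int, int] = field(default_factory=dict)

    def to_array(self) -> np.ndarray:
        """Dense counts indexed by length - length_min."""
        arr = np.zeros(self.length_max - self.length_min + 1, dtype=np.int64)
        for length, c in self.counts.items():
            arr[length - self.length_min] = c
        return arr

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("length\tcount\n")
            for length in sorted(self.counts):
                fh.write(f"{length}\t{self.counts[length]}\n")


@dataclass(frozen=True)
class Peak:
    length: int
    height: int
    prominence: float


def compute_spectrum(
    seq: GenomeSequence,
    key_length: int = DEFAULT_KEY_LENGTH,
    length_min: int = DEFAULT_LENGTH_MIN,
    length_max: int = DEFAULT_LENGTH_MAX,
) -> GRMSpectrum:
    """Accumulate consecutive-occurrence distances of all repeated k-mer keys.

    For every distinct ``key_length``-mer occurring at least twice on the
    forward strand (keys containing N are skipped), the start-to-start
    distances between consecutive occurrences are histogrammed, restricted
    to [length_min, length_max].  Deterministic for fixed inputs.
    """
    if key_length < 4:
        raise ValueError("key_length must be >= 4")
    if length_min < key_length:
        raise ValueError("length_min must be >= key_length")
    if length_max <= length_min:
        raise ValueError("length_max must exceed length_min")
    n = len(seq.residues)
    if n <= length_max:
        raise ValueError(
            f"sequence length {n} must exceed length_max {length_max}"
        )

    b = _BASE_CODE[np.frombuffer(seq.residues.encode(), dtype=np.uint8)]
    n_keys = n - key_length + 1
    codes = np.zeros(n_keys, dtype=np.int64)
    invalid = np.zeros(n_keys, dtype=bool)
    for j in range(key_length):
        col = b[j : j + n_keys]
        invalid |= col == 4
        codes = codes * 4 + np.where(col == 4, 0, col)

    pos = np.nonzero(~invalid)[0]
    codes = codes[pos]
    # Stable sort groups equal keys while preserving position order.
    order = np.argsort(codes, kind="stable")
    codes_s = codes[order]
    pos_s = pos[order]
    same_key = codes_s[1:] == codes_s[:-1]
    dists = (pos_s[1:] - pos_s[:-1])[same_key]
    dists = dists[(dists >= length_min) & (dists <= length_max)]

    spectrum = GRMSpectrum(length_min, length_max, key_length)
    lengths, counts = np.unique(dists, return_counts=True)
    spectrum.counts = {int(l): int(c) for l, c in zip(lengths, counts)}
    return spectrum


def detect_peaks(
    spec: GRMSpectrum,
    min_prominence: float | None = None,
    smoothing_window: int = 21,
) -> list[Peak]:
    """Call local maxima of the window-smoothed spectrum.

    Smoothing is a centered moving sum over ``smoothing_window`` bins.  When
    ``min_prominence`` is None it defaults to 5x the median nonzero bin
    count.  Peaks are sorted by descending prominence, ties by ascending
    length.
    """
    raw = spec.to_array()
    if raw.sum() == 0:
        return []
    if min_prominence is None:
        nonzero = raw[raw > 0]
        min_prominence = 5.0 * float(np.median(nonzero))
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window, dtype=np.int64)
        smooth = np.convolve(raw, kernel, mode="same")
    else:
        smooth = raw
    idx, props = find_peaks(smooth, prominence=min_prominence)
    peaks = [
        Peak(
            length=int(i + spec.length_min),
            height=int(smooth[i]),
            prominence=float(p),
        )
        for i, p in zip(idx, props["prominences"])
    ]
    peaks.sort(key=lambda pk: (-pk.prominence, pk.length))
    return peaks


def write_peaks_tsv(peaks: list[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("length\theight\tprominence\n")
        for p in peaks:
            fh.write(f"{p.length}\t{p.height}\t{p.prominence:.1f}\n")
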