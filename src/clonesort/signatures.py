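"""Mutational-signature refitting over the 96 single-base-substitution channels.

A mutation spectrum is the vector of counts over the 96 pyrimidine-centred
trinucleotide channels (6 substitution types x 16 flanking contexts). Given a
reference matrix of signature profiles (COSMIC-format: one column per
signature, columns summing to 1), ``refit`` decomposes an observed spectrum
into non-negative signature contributions by NNLS and normalises them to
fractions. ``group_others`` pools minor contributions (< 5% by default) into
an "others" bucket, the convention used when displaying exposure landscapes.

No de novo extraction (NMF) is performed: the reference is fixed and the fit
is a projection, which is the appropriate operation when cohort sizes are far
too small to learn signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: The 96 channels in COSMIC file order: substitution-major, then the 5' and
#: 3' flanking bases alphabetically, e.g. "A[C>A]A", "A[C>A]C", ...
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def channel_index(channel: str) -> int:
    """Position of a channel string like ``T[C>T]A`` in the standard order."""
    try:
        return _CHANNEL_INDEX[channel]
    except KeyError:
        raise ValueError(f"not a valid SBS96 channel: {channel!r}") from None


def channel_ref_alt(channel: str) -> tuple[str, str]:
    """Reference and alternate base (pyrimidine convention) of a channel."""
    channel_index(channel)
    return channel[2], channel[4]


def spectrum_from_contexts(contexts) -> np.ndarray:
    """Tally an iterable/Series of channel strings into a 96-vector.

    Entries that are missing (None/NaN, e.g. indel records) are skipped.
    """
    counts = np.zeros(96, dtype=float)
    for c in contexts:
        if c is None or (isinstance(c, float) and np.isnan(c)):
            continue
        counts[channel_index(c)] += 1
    return counts


@dataclass
class SignatureExposure:
    """Result of refitting one spectrum against a signature reference."""

    fractions: pd.Series          # signature -> contribution fraction, sums to 1
    residual_norm: float          # ||W h - x|| / ||x||
    n_mutations: float            # total count of the input spectrum
    grouped: pd.Series = field(default=None)  # filled by group_others

    def summary(self) -> pd.DataFrame:
        out = self.fractions.sort_values(ascending=False).to_frame("fraction")
        out.index.name = "signature"
        return out


def _validate_reference(reference: pd.DataFrame) -> pd.DataFrame:
    if reference.shape[0] != 96:
        raise ValueError(f"reference must have 96 rows, got {reference.shape[0]}")
    colsums = reference.to_numpy(dtype=float).sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("reference columns must each sum to 1")
    if (reference.to_numpy() < 0).any():
        raise ValueError("reference contains negative entries")
    return reference


def refit(spectrum, reference: pd.DataFrame) -> SignatureExposure:
    """Non-negative least-squares refit of a 96-channel spectrum.

    Parameters
    ----------
    spectrum : array-like of length 96
        Channel counts in :data:`SBS96_CHANNELS` order.
    reference : DataFrame, 96 x S
        Signature profiles; each column sums to 1.

    The result is invariant to rescaling the spectrum: weights are solved on
    the normalised spectrum and reported as fractions of the total.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.shape != (96,):
        raise ValueError(f"spectrum must have length 96, got {x.shape}")
    if (x < 0).any():
        raise ValueError("spectrum has negative entries")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot refit an all-zero spectrum")
    if total < 50:
        warnings.warn(
            f"refitting a spectrum of only {int(total)} mutation(s); "
            "exposures will be unstable",
            stacklevel=2,
        )
    _validate_reference(reference)
    W = reference.to_numpy(dtype=float)
    h, rnorm = nnls(W, x / total)
    s = h.sum()
    if s <= 0:  # pathological: spectrum orthogonal to every signature
        fractions = np.full(W.shape[1], 1.0 / W.shape[1])
    else:
        fractions = h / s
    return SignatureExposure(
        fractions=pd.Series(fractions, index=reference.columns),
        residual_norm=float(rnorm),
        n_mutations=float(total),
    )


def group_others(exposure: SignatureExposure, threshold: float = 0.05) -> SignatureExposure:
    """Pool signatures contributing strictly less than `threshold` into "others".

    The total fraction is conserved exactly; signatures at the threshold are
    kept (strict ``<``).
    """
    frac = exposure.fractions
    minor = frac[frac < threshold]
    major = frac[frac >= threshold]
    grouped = major.copy()
    if len(minor) > 0:
        grouped["others"] = float(minor.sum())
    exposure.grouped = grouped
    return exposure


def load_signature_reference(path) -> pd.DataFrame:
    """Read a COSMIC-format signature TSV: a Type column of channel names plus
    one column per signature. Rows are reordered to standard channel order."""
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    missing = set(SBS96_CHANNELS) - set(df.index)
    if missing:
        raise ValueError(f"reference is missing {len(missing)} channels, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(SBS96_CHANNELS)]
    return _validate_reference(df.astype(float))


def toy_reference() -> pd.DataFrame:
    """A four-signature reference for tests and synthetic data.

    Deliberately simple, deterministic profiles with the spectral character of
    the processes relevant to sun-exposed, chemotherapy-treated melanoma:

    - ``UV``         : C>T concentrated at dipyrimidines (5' C or T), the
      hallmark of UV damage (SBS7-like).
    - ``platinum``   : an even blend of C>A and T>A, echoing the
      platinum-adduct character of SBS31-like exposures.
    - ``alkylating`` : T>C biased toward 3' purines (SBS11-like flavour).
    - ``flat``       : uniform background over all 96 channels.

    This is a synthetic stand-in for the COSMIC catalogue; supply a real
    COSMIC v3 TSV via :func:`load_signature_reference` for real analyses.
    """
    channels = SBS96_CHANNELS
    ref = pd.DataFrame(0.0, index=list(channels), columns=["UV", "platinum", "alkylating", "flat"])
    for ch in channels:
        five, sub, three = ch[0], ch[2:5], ch[6]
        if sub == "C>T":
            ref.loc[ch, "UV"] = 3.0 if five in "CT" else 0.25
        if sub in ("C>A", "T>A"):
            ref.loc[ch, "platinum"] = 1.0
        if sub == "T>C":
            ref.loc[ch, "alkylating"] = 2.0 if three in "AG" else 0.5
        ref.loc[ch, "flat"] = 1.0
    ref /= ref.sum(axis=0)
    ref.index.name = "Type"
    return ref
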