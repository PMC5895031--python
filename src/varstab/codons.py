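"""Codon-usage relative adaptiveness and rare-codon cluster detection.

Relative adaptiveness rescales a codon-usage table within each synonymous
family: the most frequent codon for an amino acid is set to 100% and the
other codons are scaled linearly (100 * freq / max family freq).  A coding
sequence is profiled position by position with these values; contiguous
stretches whose sliding-window mean falls below a threshold are reported
as rare-codon clusters, where slowed translation may perturb
co-translational folding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .catalog import round_half_up
from .errors import AlphabetError, FrameError, InputError, SynonymyError

_BASES = set("ACGT")


def _codon_to_aa(genetic_code_id: int = 1) -> dict[str, str | None]:
    """Codon -> one-letter amino acid; stop codons map to None."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    mapping: dict[str, str | None] = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = None
    return mapping


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon frequencies (occurrences per 1000 codons) for one organism."""

    organism: str
    frequencies: dict[str, float]
    genetic_code_id: int = 1

    def __post_init__(self) -> None:
        expected = set(_codon_to_aa(self.genetic_code_id))
        if set(self.frequencies) != expected:
            missing = expected - set(self.frequencies)
            raise InputError(f"usage table incomplete; missing codons {sorted(missing)[:5]}")
        neg = [c for c, f in self.frequencies.items() if f < 0]
        if neg:
            raise InputError(f"negative frequencies for {neg}")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        aa = _codon_to_aa(self.genetic_code_id)
        return tuple(sorted(c for c, a in aa.items() if a is None))


@dataclass(frozen=True)
class AdaptivenessTable:
    """Per-codon relative adaptiveness in (0, 100]; stops excluded."""

    values: dict[str, float]
    ties: tuple[str, ...] = ()
    genetic_code_id: int = 1

    def rounded(self, codon: str) -> int:
        """Display value: integer percent, ties rounded half-up."""
        return int(round_half_up(self.values[codon], 0))


def load_usage_table(path: str | Path | None = None, organism: str = "custom") -> CodonUsageTable:
    """Read a TSV usage table (codon, per1000); default = embedded human table."""
    if path is None:
        ref = resources.files("varstab.data").joinpath("human_codon_usage.tsv")
        with resources.as_file(ref) as p:
            return _read_usage(p, "Homo sapiens")
    return _read_usage(Path(path), organism)


def _read_usage(path: Path, organism: str) -> CodonUsageTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"codon": str, "per1000": float})
    if not {"codon", "per1000"}.issubset(df.columns):
        raise InputError(f"{path}: expected columns 'codon' and 'per1000'")
    freqs = {row.codon.upper().replace("U", "T"): float(row.per1000) for row in df.itertuples()}
    return CodonUsageTable(organism=organism, frequencies=freqs)


def relative_adaptiveness(usage: CodonUsageTable) -> AdaptivenessTable:
    """Scale each synonymous family so its most frequent codon is 100%.

    Families whose frequencies are all zero cannot be scaled and raise.
    Ties for the family maximum give every tied codon 100 and are flagged.
    """
    aa_of = _codon_to_aa(usage.genetic_code_id)
    families: dict[str, list[str]] = {}
    for codon, aa in aa_of.items():
        if aa is not None:
            families.setdefault(aa, []).append(codon)
    values: dict[str, float] = {}
    ties: list[str] = []
    for aa, codons in families.items():
        fmax = max(usage.frequencies[c] for c in codons)
        if fmax == 0:
            raise InputError(f"all-zero frequencies for amino acid {aa!r} family")
        maxima = [c for c in codons if usage.frequencies[c] == fmax]
        if len(maxima) > 1:
            ties.extend(sorted(maxima))
        for c in codons:
            values[c] = 100.0 * usage.frequencies[c] / fmax
    return AdaptivenessTable(
        values=values, ties=tuple(ties), genetic_code_id=usage.genetic_code_id
    )


@dataclass
class CdsProfile:
    """Per-codon-position relative adaptiveness along one CDS.

    Stop codons have value NaN and are excluded from cluster statistics.
    Positions are 1-based codon indices.
    """

    codons: list[str]
    values: np.ndarray  # float; NaN at stop codons

    def __len__(self) -> int:
        return len(self.codons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.codons) + 1),
                "codon": self.codons,
                "adaptiveness": self.values,
            }
        )


def profile_cds(cds: str, adapt: AdaptivenessTable) -> CdsProfile:
    """Relative adaptiveness of each codon of an in-frame CDS."""
    seq = cds.strip().upper().replace("U", "T")
    if len(seq) == 0:
        raise InputError("empty coding sequence")
    if len(seq) % 3 != 0:
        raise FrameError(f"CDS length {len(seq)} not divisible by 3")
    stray = set(seq) - _BASES
    if stray:
        raise AlphabetError(f"non-ACGT characters in CDS: {sorted(stray)}")
    aa_of = _codon_to_aa(adapt.genetic_code_id)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    values = np.array(
        [np.nan if aa_of[c] is None else adapt.values[c] for c in codons], dtype=float
    )
    return CdsProfile(codons=codons, values=values)


def ssnp_effect(
    cds: str,
    codon_position: int,
    alt_codon: str,
    adapt: AdaptivenessTable,
) -> tuple[float, float, float]:
    """(wild-type, alternative, delta) adaptiveness of a synonymous change.

    ``codon_position`` is 1-based; ``alt_codon`` must encode the same
    amino acid as the reference codon at that position.
    """
    profile = profile_cds(cds, adapt)
    if not 1 <= codon_position <= len(profile):
        raise InputError(
            f"codon position {codon_position} outside 1..{len(profile)}"
        )
    alt = alt_codon.strip().upper().replace("U", "T")
    if len(alt) != 3 or set(alt) - _BASES:
        raise AlphabetError(f"invalid codon {alt_codon!r}")
    ref = profile.codons[codon_position - 1]
    aa_of = _codon_to_aa(adapt.genetic_code_id)
    if aa_of[ref] is None:
        raise SynonymyError(f"position {codon_position} is a stop codon")
    if aa_of[alt] != aa_of[ref]:
        raise SynonymyError(
            f"{ref}->{alt} changes the encoded amino acid "
            f"({aa_of[ref]!r} -> {aa_of[alt]!r})"
        )
    wt_value = adapt.values[ref]
    alt_value = adapt.values[alt]
    return wt_value, alt_value, alt_value - wt_value


@dataclass(frozen=True)
class RareCodonCluster:
    """A contiguous run of codon positions with low windowed adaptiveness."""

    start: int  # 1-based, closed
    end: int
    mean_adaptiveness: float


def detect_rare_clusters(
    profile: CdsProfile,
    window: int = 15,
    threshold: float = 40.0,
) -> list[RareCodonCluster]:
    """Detect stretches whose centred sliding-window mean < threshold.

    The window at position i covers [i - window//2, i + window//2] clipped
    to the profile; stop codons are excluded from every mean.  A cluster is
    the union of the extents of all below-threshold windows; overlapping or
    adjacent unions are merged, so a reported interval covers the full low
    stretch rather than only the window centres.  Deterministic for fixed
    parameters.
    """
    n = len(profile)
    if not 1 <= window <= n:
        raise InputError(f"window {window} outside 1..{n}")
    if threshold <= 0:
        raise InputError(f"threshold {threshold} must be positive")
    half = window // 2
    values = profile.values
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = values[lo:hi]
        seg = seg[~np.isnan(seg)]
        if seg.size:
            flagged[i] = seg.mean() < threshold
    # runs of flagged window centres, expanded to the windows' extents
    extents: list[list[int]] = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            lo, hi = max(0, i - half), min(n - 1, j + half)
            if extents and lo <= extents[-1][1] + 1:
                extents[-1][1] = max(extents[-1][1], hi)
            else:
                extents.append([lo, hi])
            i = j + 1
        else:
            i += 1
    clusters: list[RareCodonCluster] = []
    for lo, hi in extents:
        seg = values[lo : hi + 1]
        seg = seg[~np.isnan(seg)]
        clusters.append(
            RareCodonCluster(
                start=lo + 1,
                end=hi + 1,
                mean_adaptiveness=float(seg.mean()) if seg.size else float("nan"),
            )
        )
    return clusters


def clusters_to_frame(clusters: list[RareCodonCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"start": c.start, "end": c.end, "mean_adaptiveness": c.mean_adaptiveness}
            for c in clusters
        ],
        columns=["start", "end", "mean_adaptiveness"],
    )
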