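"""Theoretical b/y fragment spectra and experimental-vs-theoretical similarity.

The theoretical generator replaces a learned intensity predictor with
uniform-intensity b/y ions; similarity is the cosine of square-root-transformed
intensity vectors laid out over matched/unmatched peak slots. The closer the
score is to 1.0 the better the experimental spectrum supports the peptide.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

PROTON = 1.007276466
WATER = 18.0105646863

#: Monoisotopic residue masses (peptide-bond residues, Da).
MONOISOTOPIC_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Default fixed modification: carbamidomethylation of cysteine.
CARBAMIDOMETHYL: dict[str, float] = {"C": 57.02146}

DEFAULT_TOLERANCE_DA = 0.02


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """A peak list sorted ascending by m/z."""

    peaks: list[Peak]
    peptide: str | None = None
    precursor_charge: int = 1
    annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    n_matched: int
    n_theoretical: int


_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


def peptide_neutral_mass(peptide: str, fixed_mods: Mapping[str, float] | None = None) -> float:
    """Monoisotopic neutral (uncharged) peptide mass including fixed mods."""
    mods = CARBAMIDOMETHYL if fixed_mods is None else fixed_mods
    try:
        residues = sum(MONOISOTOPIC_MASS[a] + mods.get(a, 0.0) for a in peptide)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {peptide!r}") from exc
    return residues + WATER


def theoretical_spectrum(
    peptide: str,
    fragment_charges: Iterable[int] = (1,),
    ion_series: Iterable[str] = ("b", "y"),
    fixed_mods: Mapping[str, float] | None = None,
) -> Spectrum:
    """Uniform-intensity theoretical b/y spectrum of ``peptide``.

    b_i carries the first i residues plus a proton; y_i carries the last i
    residues plus water and a proton. For charge z the m/z is
    (neutral fragment + z * proton) / z. ``fixed_mods`` maps residue to mass
    delta; the default applies carbamidomethyl to C.
    """
    if len(peptide) < 2:
        raise ValueError("peptide must have length >= 2")
    if not _PEPTIDE_RE.match(peptide):
        bad = next(a for a in peptide if a not in MONOISOTOPIC_MASS)
        raise ValueError(f"unknown residue {bad!r} in {peptide!r}")
    mods = CARBAMIDOMETHYL if fixed_mods is None else fixed_mods
    series = set(ion_series)
    if not series <= {"b", "y"}:
        raise ValueError(f"unsupported ion series {series - {'b', 'y'}}")
    masses = [MONOISOTOPIC_MASS[a] + mods.get(a, 0.0) for a in peptide]
    n = len(peptide)
    prefix = [0.0]
    for m in masses:
        prefix.append(prefix[-1] + m)
    peaks: list[Peak] = []
    annotations: list[str] = []
    for i in range(1, n):
        fragments = []
        if "b" in series:
            fragments.append((f"b{i}", prefix[i]))  # neutral b fragment = residues
        if "y" in series:
            fragments.append((f"y{i}", prefix[n] - prefix[n - i] + WATER))
        for name, neutral in fragments:
            for z in fragment_charges:
                peaks.append(Peak(mz=(neutral + z * PROTON) / z, intensity=1.0))
                annotations.append(f"{name}^{z}")
    order = sorted(range(len(peaks)), key=lambda k: peaks[k].mz)
    return Spectrum(
        peaks=[peaks[k] for k in order],
        peptide=peptide,
        annotations=[annotations[k] for k in order],
    )


def match_peaks(
    experimental: Spectrum,
    theoretical: Spectrum,
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
    ppm: bool = False,
) -> list[tuple[int, int]]:
    """Greedy 1:1 peak matching within tolerance.

    Candidate (theoretical, experimental) pairs are taken in order of
    ascending |Δm/z| (ties to the lower theoretical m/z, then lower
    experimental m/z); each peak is used at most once. Returns
    (theoretical index, experimental index) pairs.
    """
    candidates: list[tuple[float, float, float, int, int]] = []
    for ti, tp in enumerate(theoretical.peaks):
        tol = tp.mz * tolerance_da * 1e-6 if ppm else tolerance_da
        for ei, ep in enumerate(experimental.peaks):
            delta = abs(ep.mz - tp.mz)
            if delta <= tol:
                candidates.append((delta, tp.mz, ep.mz, ti, ei))
    candidates.sort()
    used_t: set[int] = set()
    used_e: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, _, _, ti, ei in candidates:
        if ti in used_t or ei in used_e:
            continue
        used_t.add(ti)
        used_e.add(ei)
        matches.append((ti, ei))
    matches.sort()
    return matches


def similarity(
    experimental: Spectrum,
    theoretical: Spectrum,
    tolerance_da: float = DEFAULT_TOLERANCE_DA,
    ppm: bool = False,
    transform: str = "sqrt",
) -> SimilarityResult:
    """Cosine similarity on transformed intensities over matched peak slots.

    Unmatched peaks occupy their own slots and contribute only to the norms,
    so the score lies in [0, 1] and reaches 1 exactly for identical spectra.
    """
    if len(theoretical) == 0:
        raise ValueError("theoretical spectrum must be non-empty")
    if len(experimental) == 0:
        return SimilarityResult(score=0.0, n_matched=0, n_theoretical=len(theoretical))
    if transform == "sqrt":
        f = math.sqrt
    elif transform == "none":
        f = lambda x: x  # noqa: E731
    else:
        raise ValueError(f"unknown transform {transform!r}")
    matches = match_peaks(experimental, theoretical, tolerance_da=tolerance_da, ppm=ppm)
    cross = sum(
        f(theoretical.peaks[ti].intensity) * f(experimental.peaks[ei].intensity)
        for ti, ei in matches
    )
    norm_t = math.sqrt(sum(f(p.intensity) ** 2 for p in theoretical.peaks))
    norm_e = math.sqrt(sum(f(p.intensity) ** 2 for p in experimental.peaks))
    score = cross / (norm_t * norm_e) if norm_t > 0 and norm_e > 0 else 0.0
    return SimilarityResult(
        score=min(score, 1.0), n_matched=len(matches), n_theoretical=len(theoretical)
    )


def similarity_fractions(
    scores: Sequence[float], thresholds: Sequence[float] = (0.5, 0.7, 0.75)
) -> dict[float, float]:
    """Fraction of scores strictly above each threshold."""
    if not scores:
        raise ValueError("empty score list")
    for s in scores:
        if not 0 <= s <= 1:
            raise ValueError(f"score {s} outside [0, 1]")
    n = len(scores)
    return {t: sum(1 for s in scores if s > t) / n for t in thresholds}


# ---------------------------------------------------------------------------
# MGF IO (BEGIN IONS / END IONS dialect)
# ---------------------------------------------------------------------------

def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    lines: list[str] = []
    for i, sp in enumerate(spectra):
        lines.append("BEGIN IONS")
        title = sp.peptide or f"spectrum_{i}"
        lines.append(f"TITLE={title}")
        if sp.peptide:
            lines.append(f"SEQ={sp.peptide}")
            pepmass = (peptide_neutral_mass(sp.peptide) + sp.precursor_charge * PROTON) / (
                sp.precursor_charge
            )
            lines.append(f"PEPMASS={pepmass:.5f}")
        lines.append(f"CHARGE={sp.precursor_charge}+")
        for p in sp.peaks:
            lines.append(f"{p.mz:.5f} {p.intensity:.4f}")
        lines.append("END IONS")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    peaks: list[Peak] = []
    peptide: str | None = None
    charge = 1
    inside = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line == "BEGIN IONS":
            inside, peaks, peptide, charge = True, [], None, 1
        elif line == "END IONS":
            spectra.append(Spectrum(peaks=peaks, peptide=peptide, precursor_charge=charge))
            inside = False
        elif not inside:
            continue
        elif "=" in line:
            key, _, value = line.partition("=")
            if key == "SEQ":
                peptide = value
            elif key == "CHARGE":
                charge = int(value.rstrip("+-") or 1)
        else:
            parts = line.split()
            peaks.append(Peak(mz=float(parts[0]), intensity=float(parts[1])))
    return spectra


def write_scores_tsv(rows: Sequence[tuple[str, SimilarityResult]], path: str | Path) -> None:
    lines = ["peptide\tscore\tn_matched\tn_theoretical"]
    for peptide, res in rows:
        lines.append(f"{peptide}\t{res.score:.6f}\t{res.n_matched}\t{res.n_theoretical}")
    Path(path).write_text("\n".join(lines) + "\n")
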