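"""Peptide monoisotopic mass arithmetic, HYP ladders, library matching.

MALDI peptide ions here are singly protonated, so a feature's m/z is the
monoisotopic [M+H]+ mass: the sum of residue masses plus water plus one
proton, plus any modification deltas. The modifications that matter for
collagen-rich bone/cartilage tissue are proline hydroxylation (HYP,
+15.994915 Da — the hallmark collagen PTM stabilizing the triple helix),
methionine oxidation (same delta), N/Q deamidation (+0.984016 Da) and
N-terminal acetylation (+42.010565 Da).

Candidate m/z features are annotated against a spectral library (peptides
with site-localized or composition-level mods and theoretical [M+H]+) by
MS1 mass alone at a tight tolerance (2 mDa by default, ~1.5e-5 relative
at m/z 1300); matching reports every entry inside the tolerance, and a
feature with several isobaric matches is carried as a single ambiguous
candidate. MS/MS confirmation is outside this package's scope.

All reported masses are recomputed from sequence + mods; printed literature
values that violate mass arithmetic (e.g. ladders built by subtracting a
nominal 16) can be audited with :func:`library_discrepancy_report`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RESIDUE_MASS",
    "WATER",
    "PROTON",
    "MOD_DELTA",
    "PeptideEntry",
    "SpectralLibrary",
    "AnnotatedCandidate",
    "peptide_mz",
    "hyp_series",
    "match_features",
    "relative_mass_error",
    "recalibrate",
    "read_library_tsv",
    "write_library_tsv",
    "library_discrepancy_report",
]

# Monoisotopic residue masses (Da), standard 20 amino acids, 5 decimals.
RESIDUE_MASS = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276

MOD_DELTA = {
    "HYP": 15.994915,        # proline hydroxylation
    "oxidationM": 15.994915, # methionine oxidation
    "deamidation": 0.984016, # N/Q -> D/E
    "acetylN": 42.010565,    # N-terminal acetylation
}

# residues each localized mod may sit on
_MOD_SITES = {"HYP": "P", "oxidationM": "M", "deamidation": "NQ"}


def _validate_mods(sequence: str, mods) -> None:
    for pos, kind in mods:
        if kind not in MOD_DELTA:
            raise ValueError(f"unknown modification {kind!r}")
        if pos == "unlocalized":
            continue
        if kind == "acetylN":
            if pos != 1:
                raise ValueError("acetylN must sit at position 1 (N-terminus)")
            continue
        if not (1 <= pos <= len(sequence)):
            raise ValueError(f"mod position {pos} outside sequence (1..{len(sequence)})")
        allowed = _MOD_SITES[kind]
        residue = sequence[pos - 1]
        if residue not in allowed:
            raise ValueError(
                f"{kind} at position {pos} sits on {residue!r}; allowed: {allowed}"
            )


def peptide_mz(sequence: str, mods=()) -> float:
    """Monoisotopic [M+H]+ of a peptide with modifications.

    ``mods`` is an iterable of ``(position, kind)`` where position is a
    1-based residue index or the string ``"unlocalized"`` and kind one of
    ``HYP``, ``oxidationM``, ``deamidation``, ``acetylN``.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(RESIDUE_MASS)
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in {sequence!r}")
    mods = list(mods)
    _validate_mods(sequence, mods)
    mass = sum(RESIDUE_MASS[r] for r in sequence) + WATER + PROTON
    mass += sum(MOD_DELTA[kind] for _pos, kind in mods)
    return mass


@dataclass
class PeptideEntry:
    """A library peptide: protein, sequence, mods, theoretical [M+H]+."""

    protein: str
    sequence: str
    mods: list = field(default_factory=list)
    theoretical_mh: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.strip().upper()
        computed = peptide_mz(self.sequence, self.mods)
        if self.theoretical_mh is None:
            self.theoretical_mh = computed
        elif abs(self.theoretical_mh - computed) > 1e-6:
            raise ValueError(
                f"{self.protein} {self.sequence}: stored [M+H]+ "
                f"{self.theoretical_mh:.6f} != recomputed {computed:.6f}"
            )

    def mod_key(self) -> tuple:
        return tuple(sorted((str(p), k) for p, k in self.mods))

    def label(self) -> str:
        if not self.mods:
            return self.sequence
        return f"{self.sequence} [{_mods_to_str(self.mods)}]"


@dataclass
class SpectralLibrary:
    entries: list[PeptideEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = {}
        for e in self.entries:
            seen.setdefault((e.sequence, e.mod_key()), e)
        self.entries = list(seen.values())

    def __len__(self) -> int:
        return len(self.entries)

    def theoretical_masses(self) -> np.ndarray:
        return np.array([e.theoretical_mh for e in self.entries])


@dataclass
class AnnotatedCandidate:
    candidate: object                       # CandidateFeature
    matches: list                           # (PeptideEntry, delta_da)
    status: str                             # unique | ambiguous | unmatched

    def __post_init__(self) -> None:
        expected = (
            "unmatched" if not self.matches
            else ("unique" if len(self.matches) == 1 else "ambiguous")
        )
        if self.status != expected:
            raise ValueError(f"status {self.status!r} inconsistent with matches")


def hyp_series(sequence: str, max_hyp: int | None = None) -> list[tuple[int, float]]:
    """[M+H]+ ladder of a peptide with 0..k hydroxyprolines.

    Consecutive entries differ by exactly 15.994915 Da; k is capped at the
    number of prolines in the sequence (with a warning if ``max_hyp``
    exceeds it). A proline-free sequence yields the single unmodified
    entry.
    """
    base = peptide_mz(sequence)
    n_pro = sequence.upper().count("P")
    k = n_pro if max_hyp is None else max_hyp
    if k > n_pro:
        warnings.warn(
            f"max_hyp {k} exceeds the {n_pro} proline(s) in {sequence!r}; clipped"
        )
        k = n_pro
    return [(n, base + n * MOD_DELTA["HYP"]) for n in range(k + 1)]


def relative_mass_error(theoretical: float, observed: float) -> float:
    """|observed - theoretical| / theoretical (dimensionless)."""
    if theoretical <= 0 or observed <= 0:
        raise ValueError("masses must be positive")
    return abs(observed - theoretical) / theoretical


def recalibrate(observed_mz, ref_observed: float, ref_theoretical: float):
    """Single-point mass recalibration against the spike-in peak.

    Scales observed m/z by ``ref_theoretical / ref_observed``. Optional:
    library matching works on raw masses unless this is applied.
    """
    if ref_observed <= 0 or ref_theoretical <= 0:
        raise ValueError("reference masses must be positive")
    return np.asarray(observed_mz, float) * (ref_theoretical / ref_observed)


def match_features(
    candidates: list, library: SpectralLibrary, tol_da: float = 0.002
) -> list[AnnotatedCandidate]:
    """Annotate candidate features with all library entries within tol_da.

    Each candidate keeps every peptide whose theoretical [M+H]+ lies
    within ``tol_da`` of the observed m/z; several isobaric matches make
    the candidate ``ambiguous`` (still a single candidate feature for
    statistics), none make it ``unmatched``.
    """
    if tol_da < 0:
        raise ValueError("tol_da must be >= 0")
    if len(library) == 0:
        raise ValueError("empty spectral library")
    theo = library.theoretical_masses()
    out = []
    for cand in candidates:
        mz = float(cand.mz)
        deltas = mz - theo
        hits = np.flatnonzero(np.abs(deltas) <= tol_da)
        matches = [(library.entries[i], float(deltas[i])) for i in hits]
        matches.sort(key=lambda m: abs(m[1]))
        status = "unmatched" if not matches else ("unique" if len(matches) == 1 else "ambiguous")
        out.append(AnnotatedCandidate(candidate=cand, matches=matches, status=status))
    return out


# ---------------------------------------------------------------------------
# library TSV I/O: protein \t sequence \t mods \t mh_theoretical
# mods grammar: "HYP@9;HYP@15" (localized), "HYPx3" (unlocalized), "" (none)
# ---------------------------------------------------------------------------

def _mods_to_str(mods) -> str:
    parts = []
    unloc: dict[str, int] = {}
    for pos, kind in mods:
        if pos == "unlocalized":
            unloc[kind] = unloc.get(kind, 0) + 1
        else:
            parts.append(f"{kind}@{pos}")
    parts.extend(f"{k}x{n}" for k, n in sorted(unloc.items()))
    return ";".join(parts)


def _str_to_mods(s: str) -> list:
    s = (s or "").strip()
    if not s or s == "-":
        return []
    mods = []
    for token in s.split(";"):
        token = token.strip()
        if "@" in token:
            kind, pos = token.split("@")
            mods.append((int(pos), kind))
        elif "x" in token:
            kind, n = token.rsplit("x", 1)
            mods.extend([("unlocalized", kind)] * int(n))
        else:
            raise ValueError(f"bad mod token {token!r}")
    return mods


def read_library_tsv(path) -> SpectralLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"mods": str}, keep_default_na=False)
    required = {"protein", "sequence", "mods", "mh_theoretical"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library TSV missing columns {sorted(missing)}")
    entries = [
        PeptideEntry(
            protein=row.protein,
            sequence=row.sequence,
            mods=_str_to_mods(row.mods),
            theoretical_mh=float(row.mh_theoretical),
        )
        for row in df.itertuples()
    ]
    return SpectralLibrary(entries=entries, provenance=str(path))


def write_library_tsv(library: SpectralLibrary, path) -> None:
    pd.DataFrame(
        {
            "protein": [e.protein for e in library.entries],
            "sequence": [e.sequence for e in library.entries],
            "mods": [_mods_to_str(e.mods) for e in library.entries],
            "mh_theoretical": [f"{e.theoretical_mh:.6f}" for e in library.entries],
        }
    ).to_csv(path, sep="\t", index=False)


def library_discrepancy_report(printed: dict, library: SpectralLibrary | None = None):
    """Compare printed literature m/z values against recomputed masses.

    ``printed`` maps a label to ``(sequence, n_hyp, printed_mz)``; the
    report lists the recomputed [M+H]+, the printed value and their
    difference in mDa, flagging rows where the printed value violates
    mass arithmetic by more than 10 mDa.
    """
    rows = []
    for label, (seq, n_hyp, printed_mz) in printed.items():
        theo = peptide_mz(seq) + n_hyp * MOD_DELTA["HYP"]
        delta_mda = (printed_mz - theo) * 1000.0
        rows.append(
            {
                "label": label,
                "sequence": seq,
                "n_hyp": n_hyp,
                "recomputed_mh": theo,
                "printed_mz": printed_mz,
                "delta_mda": delta_mda,
                "violates_mass_arithmetic": abs(delta_mda) > 10.0,
            }
        )
    return pd.DataFrame(rows)
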