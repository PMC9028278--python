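"""Theoretical fragment ions for a 2PCA-derivatized linearized candidate.

The imidazolidinone formed by 2PCA conjugation at the new N-terminus adds a
residual mass of C6H3N (89.0265 Da) and fragments across two bonds flanking
the first carbonyl, giving a diagnostic pseudo a1/b1 doublet spaced by
exactly CO (27.9949 Da) that carries the first residue's side chain. A third
low-mass product, C6H7N2 at m/z 107.0609, marks the imidazolidinone itself
regardless of the conjugated residue. Gas-phase chemistry of the conjugate
is incompletely understood and hydrogen-transfer (±1 H atom) variants of the
N-terminal ions are observed; they are generated explicitly and labelled.

Conventions (see :mod:`cyclospot.chem` for the charge carrier):

* b_i = sum(first i residues) + C6H3N + proton (N-terminal ions carry 2PCA)
* a_i = b_i - CO
* y_i = sum(last i residues) + H2O + proton (never 2PCA-modified)
* internal b over spans touching neither terminus = sum(span) + proton

For disulfide-opened candidates, ions whose span covers the anchored Cys
additionally carry the disulfide-linked chain's mass.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import CO, DIAG_ION_MZ, H_ATOM, PCA_RESIDUAL, PROTON, WATER, mz, residue_masses
from .cyclic import LinearCandidate

__all__ = [
    "FragmentConfig",
    "TheoreticalFragment",
    "doublet_for_residue",
    "doublet_variants",
    "generate_fragments",
    "isobaric_internal_groups",
    "fragments_to_table",
]

ION_TYPES = ("b", "y", "a", "internal_b", "doublet", "marker")

# kinds that carry the N-terminal imidazolidinone and therefore get
# hydrogen-transfer variants
_PCA_KINDS = frozenset({"b", "a", "doublet_b", "doublet_a"})


@dataclass(frozen=True)
class FragmentConfig:
    """Which ions to generate and how.

    ``h_transfer_variants`` are integer offsets in units of one H atom
    applied to the 2PCA-bearing N-terminal ions; the default ``(0, -1)``
    covers the canonical masses plus the commonly observed one-hydrogen
    deficit. ``max_charge`` caps multiply-protonated variants of the ladder
    ions (the doublet and marker are intrinsically low-mass, singly charged).
    """

    ion_types: frozenset[str] = frozenset(ION_TYPES)
    max_charge: int = 2
    h_transfer_variants: tuple[int, ...] = (0, -1)
    include_parent_ions: bool = False

    def __post_init__(self) -> None:
        if self.max_charge < 1:
            raise ValueError("max_charge must be >= 1")
        unknown = set(self.ion_types) - set(ION_TYPES)
        if unknown:
            raise ValueError(f"unknown ion types: {sorted(unknown)}")


@dataclass(frozen=True)
class TheoreticalFragment:
    """A predicted ion: type, residue span, charge, m/z, modification flags.

    ``span`` is half-open with a 1-based start on the candidate's own
    sequence; ``h_offset`` counts H atoms added (may be negative);
    ``pca_modified`` is true iff the span includes the new N-terminus.
    """

    kind: str
    span: tuple[int, int]
    charge: int
    mz: float
    pca_modified: bool
    h_offset: int = 0
    label: str = ""


def doublet_for_residue(residue_code: str) -> tuple[float, float]:
    """Canonical (b1-type, a1-type) m/z of the diagnostic doublet.

    b1-type = residue + C6H3N + proton; a1-type = b1-type - CO. Both carry
    the first residue's side chain, so the pair names the N-terminal residue;
    their 27.9949 Da spacing is the diagnostic signature.
    """
    (r,) = residue_masses(residue_code)
    b1 = r + PCA_RESIDUAL + PROTON
    return b1, b1 - CO


def doublet_variants(
    residue_code: str, offsets: tuple[int, ...] = (0, -1)
) -> list[TheoreticalFragment]:
    """Doublet members shifted by each hydrogen-transfer offset.

    Offset k adds k × mass(H); labels record the offset (e.g. ``b1+2PCA-H``).
    """
    b1, a1 = doublet_for_residue(residue_code)
    out = []
    for k in offsets:
        for kind, base, stem in (("doublet_b", b1, "b1+2PCA"), ("doublet_a", a1, "a1+2PCA")):
            out.append(
                TheoreticalFragment(
                    kind=kind,
                    span=(1, 2),
                    charge=1,
                    mz=base + k * H_ATOM,
                    pca_modified=True,
                    h_offset=k,
                    label=stem + _h_label(k),
                )
            )
    return out


def _h_label(k: int) -> str:
    if k == 0:
        return ""
    if k == 1:
        return "+H"
    if k == -1:
        return "-H"
    return f"{k:+d}H"


def generate_fragments(
    candidate: LinearCandidate, config: FragmentConfig = FragmentConfig()
) -> list[TheoreticalFragment]:
    """All theoretical fragments of a 2PCA-derivatized candidate.

    Returns a deterministically ordered list (kind, span start, span length,
    charge, h offset). Candidates of length < 2 yield only parent-level ions
    and the marker — there is no ladder to cut.
    """
    seq = candidate.sequence
    n = len(seq)
    masses = residue_masses(seq)
    prefix = [0.0]
    for m in masses:
        prefix.append(prefix[-1] + m)
    anchor = candidate.appendage_anchor
    app = candidate.appendage_mass if anchor is not None else 0.0

    def span_mass(s: int, e: int) -> float:
        """Sum of residues in half-open 1-based span, plus appendage if covered."""
        total = prefix[e - 1] - prefix[s - 1]
        if anchor is not None and s <= anchor < e:
            total += app
        return total

    frags: list[TheoreticalFragment] = []
    want = config.ion_types
    charges = range(1, config.max_charge + 1)

    if "doublet" in want and n >= 1:
        frags.extend(doublet_variants(seq[0], config.h_transfer_variants))

    if "marker" in want:
        frags.append(
            TheoreticalFragment(
                kind="marker",
                span=(1, 1),
                charge=1,
                mz=DIAG_ION_MZ,
                pca_modified=True,
                label="marker 107.0609",
            )
        )

    if n >= 2:
        for i in range(1, n):  # ladder ordinal
            b_neutral = span_mass(1, i + 1) + PCA_RESIDUAL
            y_neutral = span_mass(n - i + 1, n + 1) + WATER
            for z in charges:
                if "b" in want:
                    for k in config.h_transfer_variants:
                        frags.append(
                            TheoreticalFragment(
                                kind="b",
                                span=(1, i + 1),
                                charge=z,
                                mz=mz(b_neutral + k * H_ATOM, z),
                                pca_modified=True,
                                h_offset=k,
                                label=f"b{i}+2PCA{_h_label(k)}"
                                + (f" ({z}+)" if z > 1 else ""),
                            )
                        )
                if "a" in want:
                    for k in config.h_transfer_variants:
                        frags.append(
                            TheoreticalFragment(
                                kind="a",
                                span=(1, i + 1),
                                charge=z,
                                mz=mz(b_neutral - CO + k * H_ATOM, z),
                                pca_modified=True,
                                h_offset=k,
                                label=f"a{i}+2PCA{_h_label(k)}"
                                + (f" ({z}+)" if z > 1 else ""),
                            )
                        )
                if "y" in want:
                    frags.append(
                        TheoreticalFragment(
                            kind="y",
                            span=(n - i + 1, n + 1),
                            charge=z,
                            mz=mz(y_neutral, z),
                            pca_modified=False,
                            label=f"y{i}" + (f" ({z}+)" if z > 1 else ""),
                        )
                    )
        if "internal_b" in want:
            for s in range(2, n):
                for e in range(s + 1, n + 1):  # span [s, e), never touches a terminus
                    neutral = span_mass(s, e)
                    for z in charges:
                        frags.append(
                            TheoreticalFragment(
                                kind="internal_b",
                                span=(s, e),
                                charge=z,
                                mz=mz(neutral, z),
                                pca_modified=False,
                                label=f"internal {seq[s - 1 : e - 1]}"
                                + (f" ({z}+)" if z > 1 else ""),
                            )
                        )

    if config.include_parent_ions:
        for z in charges:
            frags.append(
                TheoreticalFragment(
                    kind="parent",
                    span=(1, n + 1),
                    charge=z,
                    mz=mz(candidate.neutral_mass + PCA_RESIDUAL, z),
                    pca_modified=True,
                    label=f"[M+2PCA+{z}H]{z}+",
                )
            )

    frags.sort(key=lambda f: (f.kind, f.span[0], f.span[1] - f.span[0], f.charge, f.h_offset))
    return frags


def isobaric_internal_groups(
    fragments: list[TheoreticalFragment], ppm_tol: float = 10.0
) -> list[list[TheoreticalFragment]]:
    """Groups (size >= 2) of internal fragments indistinguishable within a
    ppm tolerance — e.g. permuted spans sharing one residue multiset, like
    PLK and LKP in JB1. Such groups flag ambiguous low-mass evidence that
    could suggest a false peptide start."""
    internals = sorted(
        (f for f in fragments if f.kind == "internal_b"), key=lambda f: f.mz
    )
    groups: list[list[TheoreticalFragment]] = []
    current: list[TheoreticalFragment] = []
    for f in internals:
        if current and (f.mz - current[-1].mz) / f.mz * 1e6 <= ppm_tol:
            current.append(f)
        else:
            if len({g.span for g in current}) >= 2:
                groups.append(current)
            current = [f]
    if len({g.span for g in current}) >= 2:
        groups.append(current)
    return groups


def fragments_to_table(fragments: list[TheoreticalFragment]):
    """Fragment list as a pandas DataFrame (label, kind, span, charge, mz,
    h_offset), for TSV export and inspection."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [f.label for f in fragments],
            "kind": [f.kind for f in fragments],
            "span_start": [f.span[0] for f in fragments],
            "span_end": [f.span[1] for f in fragments],
            "charge": [f.charge for f in fragments],
            "mz": [f.mz for f in fragments],
            "h_offset": [f.h_offset for f in fragments],
        }
    )
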