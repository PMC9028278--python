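"""Cyclic peptide definitions and ring-opening (linearization) enumeration.

A single amide hydrolysis of a cyclic peptide linearizes it with an
M + 18.0106 Da shift, and every possible opening site yields the same mass:
the candidates are isomers. This module enumerates that candidate space.

Two cyclization topologies are supported:

``head-to-tail``
    Backbone amide macrocycle. An n-mer has n openable amides; candidate k
    is the rotation of the written sequence starting at residue k.

``disulfide``
    Linear backbone closed into a ring by a Cys–Cys bridge. Only amides
    strictly inside the bridged loop open the ring; the opened species is
    branched (two chains joined by S–S) and is represented pseudo-linearly:
    the chain from the new N-terminus to the C-terminus, with the other
    chain's mass carried as a fixed appendage anchored on the bridged Cys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .chem import H_ATOM, WATER, peptide_mass, residue_masses

__all__ = [
    "CyclicPeptide",
    "LinearCandidate",
    "enumerate_openings",
    "candidate_for_nterm",
    "load_peptides",
]

HEAD_TO_TAIL = "head-to-tail"
DISULFIDE = "disulfide"


@dataclass(frozen=True)
class CyclicPeptide:
    """A parent cyclic peptide: residue sequence plus cyclization topology.

    ``sequence`` is the written order (e.g. ``"CYAAPLKPAKSC"``);
    ``disulfide_pair`` gives the 1-based indices of the bridged Cys residues
    and is required for (and only valid with) the disulfide topology.
    """

    name: str
    sequence: str
    topology: str = HEAD_TO_TAIL
    disulfide_pair: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        residue_masses(self.sequence)  # validates residues
        if self.topology not in (HEAD_TO_TAIL, DISULFIDE):
            raise ValueError(
                f"topology must be {HEAD_TO_TAIL!r} or {DISULFIDE!r}, "
                f"got {self.topology!r}"
            )
        if self.topology == DISULFIDE:
            if self.disulfide_pair is None:
                raise ValueError(
                    f"{self.name}: disulfide topology requires disulfide_pair"
                )
            i, j = self.disulfide_pair
            n = len(self.sequence)
            if not (1 <= i < j <= n):
                raise ValueError(f"disulfide_pair {self.disulfide_pair} out of range")
            for idx in (i, j):
                if self.sequence[idx - 1] != "C":
                    raise ValueError(
                        f"disulfide_pair index {idx} points at "
                        f"{self.sequence[idx - 1]!r}, not Cys"
                    )
            if j - i < 2:
                raise ValueError("disulfide loop must span at least one amide")
        elif self.disulfide_pair is not None:
            raise ValueError("disulfide_pair is only valid with disulfide topology")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ring_mass(self) -> float:
        """Neutral monoisotopic mass of the intact cyclic parent.

        Head-to-tail: sum of residue masses. Disulfide: linear chain mass
        minus two hydrogens for the oxidized Cys–Cys bridge.
        """
        if self.topology == HEAD_TO_TAIL:
            return peptide_mass(self.sequence, "cyclic")
        return peptide_mass(self.sequence, "linear") - 2 * H_ATOM


@dataclass(frozen=True)
class LinearCandidate:
    """One ring-opening product of a cyclic parent.

    ``opening_site`` is the 1-based index (in the parent's written sequence)
    of the residue that becomes the new N-terminus; ``sequence`` is the
    main pseudo-linear chain read from that residue. For disulfide parents
    ``appendage_mass`` carries the disulfide-linked second chain and
    ``appendage_anchor`` is the 1-based position, within ``sequence``, of the
    bridged Cys it hangs from (``None`` when fragments should ignore it).
    ``neutral_mass`` is always the full opened species, parent ring + H2O.
    """

    parent: CyclicPeptide
    opening_site: int
    sequence: str
    neutral_mass: float
    appendage_mass: float = 0.0
    appendage_anchor: Optional[int] = None

    @property
    def n_term_residue(self) -> str:
        return self.sequence[0]

    @property
    def label(self) -> str:
        return f"{self.parent.name}@{self.opening_site}{self.n_term_residue}"


def enumerate_openings(
    parent: CyclicPeptide, pseudo_linear: bool = True
) -> list[LinearCandidate]:
    """All ring-opening hydrolysis candidates of a parent, by opening site.

    Head-to-tail n-mer -> n candidates (one per backbone amide).
    Disulfide parent with bridge (i, j) -> j - i candidates: one per amide
    strictly inside the bridged loop, i.e. new N-termini at residues
    i+1 .. j. With ``pseudo_linear=False`` the disulfide appendage is kept
    in the neutral mass but not anchored for fragment generation.
    """
    seq = parent.sequence
    n = len(seq)
    total_mass = parent.ring_mass + WATER
    out: list[LinearCandidate] = []
    if parent.topology == HEAD_TO_TAIL:
        for k in range(1, n + 1):
            rotated = seq[k - 1 :] + seq[: k - 1]
            out.append(
                LinearCandidate(
                    parent=parent,
                    opening_site=k,
                    sequence=rotated,
                    neutral_mass=total_mass,
                )
            )
        return out
    i, j = parent.disulfide_pair  # type: ignore[misc]
    for k in range(i + 1, j + 1):
        main = seq[k - 1 :]
        other = seq[: k - 1]
        # oxidized bridge: the two chains share a 2-H loss
        appendage = peptide_mass(other, "linear") - 2 * H_ATOM
        out.append(
            LinearCandidate(
                parent=parent,
                opening_site=k,
                sequence=main,
                neutral_mass=total_mass,
                appendage_mass=appendage,
                appendage_anchor=(j - k + 1) if pseudo_linear else None,
            )
        )
    return out


def candidate_for_nterm(
    parent: CyclicPeptide, residue_code: str, pseudo_linear: bool = True
) -> list[LinearCandidate]:
    """Candidates whose new N-terminus is the given residue (may be empty).

    This is the duplicate-residue lookup: when the diagnostic doublet names
    the first residue, every occurrence of that residue in the ring is a
    possible opening site and must be disambiguated by its y-ion ladder.
    """
    return [
        c
        for c in enumerate_openings(parent, pseudo_linear=pseudo_linear)
        if c.n_term_residue == residue_code
    ]


def load_peptides(path: str) -> dict[str, CyclicPeptide]:
    """Read peptide definitions from a YAML (or JSON) config file.

    Expected layout::

        peptides:
          - name: JB1
            sequence: CYAAPLKPAKSC
            topology: head-to-tail
          - name: somatostatin
            sequence: AGCKNFFWKTFTSC
            topology: disulfide
            disulfide_pair: [3, 14]
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["peptides"] if isinstance(doc, dict) and "peptides" in doc else doc
    peptides: dict[str, CyclicPeptide] = {}
    for entry in entries:
        pair = entry.get("disulfide_pair")
        pep = CyclicPeptide(
            name=entry["name"],
            sequence=entry["sequence"],
            topology=entry.get("topology", HEAD_TO_TAIL),
            disulfide_pair=tuple(pair) if pair else None,
        )
        peptides[pep.name] = pep
    return peptides
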