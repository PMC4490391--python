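"""Methylation-motif site finding on a reference sequence.

Methyltransferase recognition motifs are written as IUPAC strings, e.g.
``GATC``, ``RGATCY`` or the bipartite type III motif ``TCANNNNNNTRG`` where
an N-run encodes a fixed-length spacer.  A motif specification also carries
the 0-based offset of the methylated base within the motif, since the
kinetic signal is read at exactly that base.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

from .records import FORWARD, REVERSE

log = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement; characters outside ACGT map to themselves
    complemented where defined, otherwise to 'N' (which never matches)."""
    out = seq.translate(_DNA_COMPLEMENT)[::-1]
    return re.sub("[^ACGTacgt]", "N", out)


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC methylation motif with the index of the modified base."""

    iupac: str
    modified_index: int
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "iupac", self.iupac.upper())
        if not self.name:
            object.__setattr__(self, "name", self.iupac)
        for c in self.iupac:
            if c not in IUPAC:
                raise ValueError(f"invalid IUPAC character {c!r} in motif {self.iupac}")
        if not 0 <= self.modified_index < len(self.iupac):
            raise ValueError(
                f"modified_index {self.modified_index} outside motif of length {len(self.iupac)}"
            )
        if self.iupac[self.modified_index] == "N":
            raise ValueError("the modified base may not be an N spacer position")

    @property
    def modified_base(self) -> str:
        return self.iupac[self.modified_index]

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True, order=True)
class MotifSite:
    """Modified-base position of one motif occurrence on one strand."""

    ref_pos: int
    strand: int
    motif_name: str = field(compare=False, default="")


def _regex(motif: MotifSpec) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported (scan step 1)
    body = "".join("[" + IUPAC[c] + "]" for c in motif.iupac)
    return re.compile("(?=" + body + ")")


def find_motif_sites(
    reference: str, motif: MotifSpec, both_strands: bool = True
) -> list[MotifSite]:
    """Locate every occurrence of ``motif`` on the reference.

    Forward-strand sites come from scanning the reference directly; reverse
    strand sites from scanning its reverse complement, with the coordinate of
    the modified base mapped back to forward coordinates.  Reference letters
    outside A/C/G/T never match.  Results are sorted by (ref_pos, strand).
    """
    ref = reference.upper()
    pat = _regex(motif)
    sites = [
        MotifSite(m.start() + motif.modified_index, FORWARD, motif.name)
        for m in pat.finditer(ref)
    ]
    if both_strands:
        rc = reverse_complement(ref)
        n = len(ref)
        sites.extend(
            MotifSite(n - 1 - (m.start() + motif.modified_index), REVERSE, motif.name)
            for m in pat.finditer(rc)
        )
    sites.sort(key=lambda s: (s.ref_pos, s.strand))
    return sites


def expand_degenerate(motif: MotifSpec) -> list[MotifSpec]:
    """Cartesian expansion of a degenerate motif into explicit motifs.

    N spacers (bipartite motifs) are refused: they are structural, not
    hypotheses about the recognized bases.
    """
    if "N" in motif.iupac:
        raise ValueError("bipartite motifs with N spacers cannot be expanded")
    choices = [IUPAC[c] for c in motif.iupac]
    out = []
    for combo in itertools.product(*choices):
        explicit = "".join(combo)
        out.append(
            MotifSpec(explicit, motif.modified_index, name=f"{motif.name}:{explicit}")
        )
    return out


def parse_motif_arg(text: str) -> MotifSpec:
    """Parse the ``IUPAC:modified_index`` command-line shorthand.

    Without an explicit index, 6mA conventions apply: the first adenine
    (an A or the first purine-compatible base) is assumed modified, with a
    logged warning.
    """
    if ":" in text:
        iupac, _, idx = text.partition(":")
        return MotifSpec(iupac, int(idx))
    iupac = text.upper()
    for i, c in enumerate(iupac):
        if "A" in IUPAC[c]:
            log.warning(
                "motif %s given without modified_index; defaulting to first "
                "adenine-compatible position %d", iupac, i,
            )
            return MotifSpec(iupac, i)
    raise ValueError(
        f"motif {iupac} has no adenine-compatible base; supply modified_index "
        "explicitly as MOTIF:INDEX"
    )


def read_motif_table(path) -> list[MotifSpec]:
    """Read a motif list TSV with columns: name, iupac, modified_index."""
    motifs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["name", "iupac", "modified_index"]:
            raise ValueError(f"unexpected motif table header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            name, iupac, idx = parts
            motifs.append(MotifSpec(iupac, int(idx), name=name))
    return motifs
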