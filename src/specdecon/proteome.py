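"""In-silico digestion, shuffled decoys, I/L grouping and entrapment databases.

Decoys are per-peptide shuffles that preserve length, amino-acid composition
and the C-terminal residue (so tryptic decoys stay tryptic).  Entrapment
proteins are built by shuffling every tryptic segment of a target protein in
place, which preserves the digest-peptide length spectrum of the database
while producing sequences known to be absent from the sample.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import fasta as _fasta

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

# cleavage rules: regex matching the residue *after which* the backbone is cut
CLEAVAGE_RULES = {
    "trypsin": r"[KR](?!P)",
    "trypsin/p": r"[KR]",
    "lysc": r"K",
    "argc": r"R",
}


def il_key(sequence: str) -> str:
    """Collapse I and L to J: peptides indistinguishable by fragment mass."""
    return sequence.replace("I", "J").replace("L", "J")


@dataclass
class Peptide:
    sequence: str
    modifications: tuple[tuple[int | str, float, str], ...] = ()
    is_decoy: bool = False
    is_entrapment: bool = False
    protein_ids: frozenset[str] = field(default_factory=frozenset)
    missed_cleavages: int = 0
    unshufflable: bool = False

    @property
    def il_group_key(self) -> str:
        return il_key(self.sequence)

    @property
    def mod_key(self) -> tuple:
        return tuple(sorted((name, round(delta, 4)) for _, delta, name in self.modifications))

    def __hash__(self) -> int:
        return hash((self.sequence, self.modifications, self.is_decoy, self.is_entrapment))


def _cleavage_sites(sequence: str, rule: str) -> list[int]:
    """0-based positions i such that the bond after residue i is cleaved."""
    return [m.start() for m in re.finditer(rule, sequence) if m.start() < len(sequence) - 1]


def digest_protein(
    protein_sequence: str,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    length_range: tuple[int, int] = (7, 30),
    protein_id: str = "",
) -> list[Peptide]:
    """Enzymatic in-silico digest of one protein.

    Returns every peptide within the length bounds carrying at most
    ``max_missed`` internal cleavage sites, annotated with its missed-cleavage
    count and source protein.
    """
    seq = protein_sequence.strip().upper()
    bad = [i for i, c in enumerate(seq) if c not in VALID_AA]
    if bad:
        raise ValueError(
            f"non-amino-acid character {seq[bad[0]]!r} at position {bad[0] + 1}"
            + (f" of protein {protein_id}" if protein_id else "")
        )
    rule = CLEAVAGE_RULES.get(enzyme.lower(), enzyme)
    sites = _cleavage_sites(seq, rule)
    # fragment boundaries: starts at 0 and site+1; ends at site+1 and len
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    lo, hi = length_range
    out: list[Peptide] = []
    nseg = len(bounds) - 1
    for i in range(nseg):
        for j in range(i + 1, min(i + 1 + max_missed + 1, nseg + 1)):
            pep = seq[bounds[i] : bounds[j]]
            if lo <= len(pep) <= hi:
                out.append(
                    Peptide(
                        sequence=pep,
                        protein_ids=frozenset([protein_id] if protein_id else []),
                        missed_cleavages=j - i - 1,
                    )
                )
    return out


def digest_fasta(
    path: str | Path,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    length_range: tuple[int, int] = (7, 30),
) -> list[Peptide]:
    """Digest every protein of a FASTA file; duplicate peptides across proteins
    are merged with the union of their protein ids."""
    merged: dict[tuple[str, int], Peptide] = {}
    with _fasta.FASTA(str(path)) as reader:
        for header, seq in reader:
            pid = header.split()[0]
            for pep in digest_protein(seq, enzyme, max_missed, length_range, pid):
                key = (pep.sequence, pep.missed_cleavages)
                if key in merged:
                    old = merged[key]
                    merged[key] = Peptide(
                        sequence=pep.sequence,
                        protein_ids=old.protein_ids | pep.protein_ids,
                        missed_cleavages=pep.missed_cleavages,
                        is_entrapment=old.is_entrapment and pep.is_entrapment,
                    )
                else:
                    pep = Peptide(
                        sequence=pep.sequence,
                        protein_ids=pep.protein_ids,
                        missed_cleavages=pep.missed_cleavages,
                        is_entrapment=all(p.startswith("ENTRAP_") for p in pep.protein_ids),
                    )
                    merged[key] = pep
    return list(merged.values())


def _peptide_rng(seed: int, sequence: str, salt: int = 0) -> np.random.Generator:
    h = hashlib.blake2b(f"{seed}|{salt}|{sequence}".encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(h, "little"))


def _shuffle_keep_cterm(sequence: str, rng: np.random.Generator) -> str:
    body = list(sequence[:-1])
    rng.shuffle(body)
    return "".join(body) + sequence[-1]


def generate_decoys(
    peptides: list[Peptide], seed: int = 0, max_retries: int = 20
) -> list[Peptide]:
    """One shuffled decoy per target peptide.

    Each decoy preserves length, composition and the C-terminal residue.
    Shuffles colliding (on the I/L-collapsed key) with any target are retried
    up to ``max_retries`` times, then a reversal fallback is tried; peptides
    with no collision-free permutation are emitted flagged ``unshufflable``
    and must be excluded from scoring.  Deterministic under ``seed``.
    """
    target_keys = {p.il_group_key for p in peptides}
    out: list[Peptide] = []
    for pep in peptides:
        seq = pep.sequence
        decoy_seq = None
        for retry in range(max_retries):
            cand = _shuffle_keep_cterm(seq, _peptide_rng(seed, seq, retry))
            if il_key(cand) not in target_keys:
                decoy_seq = cand
                break
        if decoy_seq is None:
            cand = seq[:-1][::-1] + seq[-1]
            if il_key(cand) not in target_keys:
                decoy_seq = cand
        if decoy_seq is None:
            out.append(
                Peptide(
                    sequence=seq,
                    modifications=pep.modifications,
                    is_decoy=True,
                    protein_ids=pep.protein_ids,
                    missed_cleavages=pep.missed_cleavages,
                    unshufflable=True,
                )
            )
        else:
            out.append(
                Peptide(
                    sequence=decoy_seq,
                    modifications=pep.modifications,
                    is_decoy=True,
                    is_entrapment=pep.is_entrapment,
                    protein_ids=pep.protein_ids,
                    missed_cleavages=pep.missed_cleavages,
                )
            )
    return out


def select_il_representatives(
    peptides: list[Peptide],
) -> dict[str, tuple[Peptide, list[Peptide]]]:
    """Group peptides by I/L-collapsed key; the representative of each group is
    the lexicographically smallest member.  Scoring runs on representatives
    only; members are expanded back afterwards with identical scores."""
    groups: dict[tuple, list[Peptide]] = {}
    for pep in peptides:
        groups.setdefault((pep.il_group_key, pep.mod_key, pep.is_decoy), []).append(pep)
    out: dict[str, tuple[Peptide, list[Peptide]]] = {}
    for (key, mod_key, is_decoy), members in groups.items():
        members = sorted(members, key=lambda p: p.sequence)
        full_key = f"{key}|{mod_key}|{'D' if is_decoy else 'T'}"
        out[full_key] = (members[0], members)
    return out


def build_entrapment_db(
    target_fasta: str | Path,
    out_fasta: str | Path,
    multiplier: int = 1,
    seed: int = 0,
    enzyme: str = "trypsin",
    length_range: tuple[int, int] = (7, 30),
    max_retries: int = 20,
) -> Path:
    """Write a FASTA of entrapment proteins: per-segment shuffles of the targets.

    Each target protein yields ``multiplier`` entrapment proteins whose tryptic
    segments are independent shuffles (C-terminal residue kept).  Segments in
    the searched length range that still collide with a target peptide after
    retries are excised, so the entrapment digest never overlaps the target
    digest on the I/L-collapsed key.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    target_fasta = Path(target_fasta)
    rule = CLEAVAGE_RULES.get(enzyme.lower(), enzyme)
    with _fasta.FASTA(str(target_fasta)) as reader:
        proteins = [(h.split()[0], seq.upper()) for h, seq in reader]

    target_keys: set[str] = set()
    for _, seq in proteins:
        for pep in digest_protein(seq, enzyme, 2, length_range):
            target_keys.add(pep.il_group_key)

    def shuffle_segment(seg: str, rng: np.random.Generator) -> str:
        # permute only residues that cannot create or destroy cleavage sites
        # (K/R define sites, P suppresses them), so the entrapment protein
        # digests into exactly the same fragment structure as its target
        body = list(seg)
        idx = [i for i, c in enumerate(body) if c not in "KRP"]
        vals = [body[i] for i in idx]
        rng.shuffle(vals)
        for i, v in zip(idx, vals):
            body[i] = v
        return "".join(body)

    def colliding_keys(segments: list[str]) -> set[int]:
        """Indices of segments participating in a colliding digest peptide."""
        bad: set[int] = set()
        nseg = len(segments)
        lo, hi = length_range
        for i in range(nseg):
            for j in range(i + 1, min(i + 4, nseg + 1)):  # up to 2 missed
                pep = "".join(segments[i:j])
                if lo <= len(pep) <= hi and il_key(pep) in target_keys:
                    bad.update(range(i, j))
        return bad

    entries = []
    for copy in range(multiplier):
        for pid, seq in proteins:
            sites = _cleavage_sites(seq, rule)
            bounds = [0] + [s + 1 for s in sites] + [len(seq)]
            base_segments = [seq[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
            segments = None
            for retry in range(max_retries):
                rng = _peptide_rng(seed, f"{copy}|{pid}", retry)
                cand = [shuffle_segment(s, rng) for s in base_segments]
                if not colliding_keys(cand):
                    segments = cand
                    break
            if segments is None:
                # excise the offending segments: unavoidable collisions
                # (e.g. segments with < 2 shuffleable residues)
                rng = _peptide_rng(seed, f"{copy}|{pid}", max_retries)
                segments = [shuffle_segment(s, rng) for s in base_segments]
                while True:
                    bad = colliding_keys(segments)
                    if not bad:
                        break
                    segments = [s for i, s in enumerate(segments) if i != min(bad)]
            entries.append(
                (f"ENTRAP_{copy}_{pid} entrapment_ratio={multiplier}", "".join(segments))
            )

    out_fasta = Path(out_fasta)
    _fasta.write(entries, str(out_fasta), file_mode="w")
    return out_fasta
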