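"""Mutation token grammar and sequence editing.

Tokens follow the compact notation used throughout the phase-separation
engineering literature: ``R106C`` substitutes Arg106 by Cys, ``H5-``
deletes His5.  Any Unicode hyphen/dash variant in a deletion token is
normalized to the ASCII hyphen on input; output is always ASCII.

Positions are 1-based.  Multi-site edit sets are applied in descending
position order so that deletions never shift the coordinates of edits
still to be applied.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .sequences import AA_INDEX, ProteinSequence

# every dash-like codepoint we are willing to read as a deletion marker
_DASH_VARIANTS = "-‐‑‒–—―−﹣－"
_TOKEN_RE = re.compile(r"^([A-Z])(\d+)([A-Z]|-)$")


class MutationError(ValueError):
    """Malformed token, failed reference check, or invalid edit set."""


def _normalize_dashes(token: str) -> str:
    out = token.strip()
    for d in _DASH_VARIANTS[1:]:
        out = out.replace(d, "-")
    return out


@dataclass(frozen=True, order=True)
class MutationSpec:
    """A single substitution or single-residue deletion.

    ``kind`` is ``"substitution"`` or ``"deletion"``; ``alt_aa`` is None
    for deletions.  ``position`` is 1-based.
    """

    position: int
    ref_aa: str
    alt_aa: str | None = None
    kind: str = field(default="substitution")

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion"):
            raise MutationError(f"unknown mutation kind {self.kind!r}")
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in AA_INDEX:
            raise MutationError(f"non-canonical reference residue {self.ref_aa!r}")
        if self.kind == "substitution":
            if self.alt_aa is None:
                raise MutationError("substitution requires an alternate residue")
            if self.alt_aa not in AA_INDEX:
                raise MutationError(
                    f"non-canonical alternate residue {self.alt_aa!r}"
                )
            if self.alt_aa == self.ref_aa:
                raise MutationError(
                    f"substitution {self.ref_aa}{self.position}{self.alt_aa} "
                    "does not change the residue"
                )
        elif self.alt_aa is not None:
            raise MutationError("deletion must not carry an alternate residue")

    @property
    def is_deletion(self) -> bool:
        return self.kind == "deletion"


def parse_mutation_token(token: str) -> MutationSpec:
    """Parse one token (``R106C``, ``H5-``, ``A326P``) into a spec.

    Unicode dash variants are accepted for deletions and normalized.
    """
    normalized = _normalize_dashes(token)
    m = _TOKEN_RE.match(normalized)
    if m is None:
        raise MutationError(f"malformed mutation token {token!r}")
    ref, pos_s, alt = m.groups()
    position = int(pos_s)
    if position == 0:
        raise MutationError(f"position 0 in token {token!r} (positions are 1-based)")
    if alt == "-":
        return MutationSpec(position=position, ref_aa=ref, kind="deletion")
    return MutationSpec(position=position, ref_aa=ref, alt_aa=alt)


def format_mutation_token(spec: MutationSpec) -> str:
    """Canonical ASCII token for a spec; inverse of :func:`parse_mutation_token`."""
    if spec.is_deletion:
        return f"{spec.ref_aa}{spec.position}-"
    return f"{spec.ref_aa}{spec.position}{spec.alt_aa}"


class MutationSet:
    """An ordered set of edits against one parent sequence.

    No two edits may share a position.  Iteration and application run in
    descending position order, which keeps 1-based coordinates stable in
    the presence of deletions.
    """

    def __init__(self, specs: Iterable[MutationSpec] = ()) -> None:
        specs = list(specs)
        seen: set[int] = set()
        for s in specs:
            if s.position in seen:
                raise MutationError(
                    f"multiple edits at position {s.position} in one mutation set"
                )
            seen.add(s.position)
        self.specs: tuple[MutationSpec, ...] = tuple(
            sorted(specs, key=lambda s: -s.position)
        )

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "MutationSet":
        return cls(parse_mutation_token(t) for t in tokens)

    def tokens(self) -> list[str]:
        """Canonical tokens in ascending position order (reporting order)."""
        return [format_mutation_token(s) for s in sorted(self.specs)]

    @property
    def has_mixed_kinds(self) -> bool:
        """True when the set mixes deletions and substitutions (flagged in reports)."""
        kinds = {s.kind for s in self.specs}
        return len(kinds) > 1

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationSet) and self.specs == other.specs

    def __hash__(self) -> int:
        return hash(self.specs)

    def __repr__(self) -> str:
        return f"MutationSet({'+'.join(self.tokens()) or 'identity'})"


def validate_against(seq: ProteinSequence, muts: MutationSet) -> None:
    """Check every edit's reference residue and range against ``seq``.

    Raises :class:`MutationError` listing position, expected and found
    residue on the first disagreement.
    """
    for spec in muts:
        if spec.position > len(seq):
            raise MutationError(
                f"position {spec.position} out of range for {seq.id!r} "
                f"(length {len(seq)})"
            )
        found = seq.residue_at(spec.position)
        if found != spec.ref_aa:
            raise MutationError(
                f"reference mismatch at position {spec.position} of {seq.id!r}: "
                f"token expects {spec.ref_aa}, sequence has {found}"
            )


def apply_mutation_set(seq: ProteinSequence, muts: MutationSet) -> ProteinSequence:
    """Apply validated edits; deletions shorten the sequence by one each.

    The empty set returns a sequence identical to the parent (new id
    suffix omitted).
    """
    validate_against(seq, muts)
    if len(muts) == 0:
        return ProteinSequence(id=seq.id, residues=seq.residues)
    chars = list(seq.residues)
    for spec in muts:  # descending position order
        if spec.is_deletion:
            del chars[spec.position - 1]
        else:
            chars[spec.position - 1] = spec.alt_aa
    label = f"{seq.id}|{'+'.join(muts.tokens())}"
    return ProteinSequence(id=label, residues="".join(chars))


def read_mutation_table(path: str | Path) -> list[dict]:
    """Read a CSV mutation table with columns ``protein_id,token[,label]``.

    Returns a list of dicts with parsed ``spec`` plus the raw fields;
    ``label`` is None when the column is absent or empty.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"protein_id", "token"} <= set(
            reader.fieldnames
        ):
            raise MutationError(
                f"{path}: mutation tables need at least columns protein_id,token"
            )
        for row in reader:
            label = row.get("label")
            rows.append(
                {
                    "protein_id": row["protein_id"],
                    "token": row["token"],
                    "spec": parse_mutation_token(row["token"]),
                    "label": int(label) if label not in (None, "") else None,
                }
            )
    return rows


def write_mutation_table(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein_id", "token", "label"])
        for row in rows:
            writer.writerow(
                [row["protein_id"], row["token"],
                 "" if row.get("label") is None else row["label"]]
            )
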