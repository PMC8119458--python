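"""Secondary-structure annotation: dot-bracket plus explicit non-WC pairs.

File format (1-based residue positions)::

    GCGCAAGC          # line 1: sequence
    ((.[..))          # line 2: dot-bracket; ()[]{}<> all accepted,
                      # extra bracket families encode pseudoknots
    3 6 NWC           # subsequent lines: explicit non-Watson-Crick pairs
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PairingAnnotation", "PairingError", "parse_dot_bracket",
           "read_pairing", "parse_pairing_text"]

_BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


class PairingError(ValueError):
    pass


def parse_dot_bracket(db: str) -> list[tuple[int, int]]:
    """Return 0-based (i, j) pairs, i < j, from a dot-bracket string."""
    stacks: dict[str, list[int]] = {k: [] for k in _BRACKETS}
    pairs = []
    for pos, ch in enumerate(db):
        if ch in _BRACKETS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise PairingError(f"unbalanced {ch!r} at position {pos + 1}")
            pairs.append((stacks[opener].pop(), pos))
        elif ch not in ".-":
            raise PairingError(f"unexpected character {ch!r} in dot-bracket")
    for opener, stack in stacks.items():
        if stack:
            raise PairingError(
                f"unbalanced {opener!r} at position {stack[-1] + 1}"
            )
    return sorted(pairs)


@dataclass
class PairingAnnotation:
    """Sequence plus WC and non-WC pair lists (0-based, i < j)."""

    sequence: str
    wc_pairs: list[tuple[int, int]] = field(default_factory=list)
    nwc_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.sequence)
        self.wc_pairs = [tuple(sorted(p)) for p in self.wc_pairs]
        self.nwc_pairs = [tuple(sorted(p)) for p in self.nwc_pairs]
        seen: set[int] = set()
        for i, j in self.wc_pairs + self.nwc_pairs:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise PairingError(f"pair ({i + 1},{j + 1}) out of range")
        for i, j in self.wc_pairs:
            if i in seen or j in seen:
                raise PairingError(
                    f"residue in more than one WC pair near ({i + 1},{j + 1})"
                )
            seen.update((i, j))

    def wc_partner(self) -> dict[int, int]:
        out = {}
        for i, j in self.wc_pairs:
            out[i] = j
            out[j] = i
        return out

    def paired(self) -> set[int]:
        s = set()
        for i, j in self.wc_pairs + self.nwc_pairs:
            s.update((i, j))
        return s


def step_class(ann: PairingAnnotation, i: int) -> str:
    """Class of the sequence step i -> i+1 (0-based).

    'wc-nb' when the two residues form consecutive pairs of one WC
    helix; 'nwc-nb' when both residues are paired but not as a WC helix
    step (NWC regions and WC<->NWC junctions); 'loop-nb' otherwise.
    """
    wc = ann.wc_partner()
    paired = ann.paired()
    if (i in wc and i + 1 in wc and wc[i] == wc[i + 1] + 1):
        return "wc-nb"
    if i in paired and i + 1 in paired:
        return "nwc-nb"
    return "loop-nb"


def parse_pairing_text(text: str) -> PairingAnnotation:
    lines = [ln.strip() for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if len(lines) < 2:
        raise PairingError("need at least a sequence and a dot-bracket line")
    seq = lines[0].upper()
    db = lines[1].split("#")[0].strip()
    if len(db) != len(seq):
        raise PairingError(
            f"dot-bracket length {len(db)} != sequence length {len(seq)}"
        )
    wc = parse_dot_bracket(db)
    nwc = []
    for ln in lines[2:]:
        parts = ln.split()
        if len(parts) != 3 or parts[2].upper() != "NWC":
            raise PairingError(f"cannot parse pair line {ln!r}")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        nwc.append((i, j))
    return PairingAnnotation(seq, wc, nwc)


def read_pairing(path) -> PairingAnnotation:
    with open(path) as fh:
        return parse_pairing_text(fh.read())


def write_pairing(annotation: PairingAnnotation, path) -> None:
    n = len(annotation.sequence)
    db = ["."] * n
    # nested pairs with (), crossing pairs promoted to [] then {}
    families = ["()", "[]", "{}", "<>"]
    placed: list[list[tuple[int, int]]] = [[] for _ in families]
    for i, j in sorted(annotation.wc_pairs):
        for fam, group in enumerate(placed):
            if all(not (a < i < b < j or i < a < j < b) for a, b in group):
                group.append((i, j))
                db[i], db[j] = families[fam][0], families[fam][1]
                break
        else:
            raise PairingError("too many crossing pair families to encode")
    with open(path, "w") as fh:
        fh.write(annotation.sequence + "\n")
        fh.write("".join(db) + "\n")
        for i, j in annotation.nwc_pairs:
            fh.write(f"{i + 1} {j + 1} NWC\n")
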