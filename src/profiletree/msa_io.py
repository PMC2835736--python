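"""Alignment and tree input/output.

Reads aligned FASTA and interleaved Phylip through Biopython, canonicalizes
sequences (uppercase, ``U``->``T`` for nucleotides, ambiguity codes treated
as gaps), deduplicates byte-identical rows, and reads/writes Newick.

Design conventions
------------------
* Ambiguity codes (nucleotide ``N/R/Y/...``, amino-acid ``B/Z/X``) are mapped
  to gaps: a fully uncertain character carries no information in a profile.
* The gap character set is ``{'-', '.'}`` plus the mapped ambiguity codes.
* Newick output carries local supports as internal node labels and branch
  lengths formatted ``%.5f`` by default; the top-level trifurcation is
  preserved.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
from Bio import AlignIO, SeqIO

from .tree import Node, Tree, collapse_root_bifurcation

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

_NT_KEEP = set(NT_ALPHABET)
_AA_KEEP = set(AA_ALPHABET)
_NT_AUTO = set("ACGTUN")


@dataclass
class Alignment:
    """An aligned character matrix over a declared alphabet.

    ``rows`` are uppercase strings of identical length over the alphabet
    plus ``'-'``; ``dedup_map`` maps a representative name to the names of
    byte-identical duplicates that were collapsed into it.
    """

    names: list[str]
    rows: list[str]
    alphabet: str  # "nt" or "aa"
    dedup_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def letters(self) -> str:
        return NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]


class AlignmentError(ValueError):
    pass


def _canonicalize(seq: str, alphabet: str) -> str:
    s = seq.upper().replace(".", "-")
    if alphabet == "nt":
        s = s.replace("U", "T")
        keep = _NT_KEEP
    else:
        keep = _AA_KEEP
    return "".join(c if c in keep else "-" for c in s)


def _detect_alphabet(seqs: list[str]) -> str:
    """nt iff at least 95% of non-gap characters look nucleotide-like."""
    nongap = ntish = 0
    for s in seqs:
        for c in s.upper():
            if c in "-.":
                continue
            nongap += 1
            if c in _NT_AUTO:
                ntish += 1
    if nongap == 0:
        raise AlignmentError("alignment contains no characters")
    return "nt" if ntish / nongap >= 0.95 else "aa"


def _read_records(handle, fmt: str) -> list[tuple[str, str]]:
    if fmt == "fasta":
        return [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]
    if fmt in ("phylip", "phylip-interleaved"):
        aln = AlignIO.read(handle, "phylip-relaxed")
        return [(r.id, str(r.seq)) for r in aln]
    raise AlignmentError(f"unknown alignment format: {fmt!r}")


def read_alignment(path, format: str = "auto", alphabet: str = "auto") -> Alignment:
    """Read an aligned FASTA or interleaved Phylip file.

    Raises :class:`AlignmentError` on an empty file, ragged rows (naming the
    offending sequence), or duplicate names.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    if not text.strip():
        raise AlignmentError("empty alignment file")
    if format == "auto":
        format = "fasta" if text.lstrip().startswith(">") else "phylip"
    records = _read_records(io.StringIO(text), format)
    if not records:
        raise AlignmentError("no sequences found")
    names = [n for n, _ in records]
    if len(set(names)) != len(names):
        dup = next(n for i, n in enumerate(names) if n in names[:i])
        raise AlignmentError(f"duplicate sequence name: {dup!r}")
    length = len(records[0][1])
    for name, seq in records:
        if len(seq) != length:
            raise AlignmentError(
                f"ragged alignment: sequence {name!r} has length "
                f"{len(seq)}, expected {length}")
    raw = [seq for _, seq in records]
    if alphabet == "auto":
        alphabet = _detect_alphabet(raw)
    rows = [_canonicalize(s, alphabet) for s in raw]
    return Alignment(names=names, rows=rows, alphabet=alphabet)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    close = False
    if not hasattr(path, "write"):
        path = open(path, "w")
        close = True
    try:
        if format == "fasta":
            for name, row in zip(aln.names, aln.rows):
                path.write(f">{name}\n{row}\n")
        elif format in ("phylip", "phylip-interleaved"):
            path.write(f" {aln.n} {aln.length}\n")
            for name, row in zip(aln.names, aln.rows):
                path.write(f"{name:<10s} {row}\n")
        else:
            raise AlignmentError(f"unknown alignment format: {format!r}")
    finally:
        if close:
            path.close()


# --------------------------------------------------------------------------
# Deduplication

def deduplicate(aln: Alignment) -> Alignment:
    """Collapse byte-identical rows; the first occurrence is representative.

    Tree inference runs on the distinct rows; :func:`reattach_duplicates`
    restores the duplicates as zero-length siblings afterwards.
    """
    seen: dict[str, str] = {}
    names, rows = [], []
    dedup: dict[str, list[str]] = {}
    for name, row in zip(aln.names, aln.rows):
        if row in seen:
            dedup.setdefault(seen[row], []).append(name)
        else:
            seen[row] = name
            names.append(name)
            rows.append(row)
    return Alignment(names=names, rows=rows, alphabet=aln.alphabet,
                     dedup_map=dedup)


def reattach_duplicates(tree: Tree, dedup_map: dict[str, list[str]]) -> Tree:
    """Re-attach collapsed duplicates as zero-length cherries.

    Each representative leaf becomes the start of a chain of zero-length
    internal nodes so the output stays fully bifurcating.
    """
    if not dedup_map:
        return tree
    by_name = {leaf.name: leaf for leaf in tree.leaves()}
    for rep, dups in dedup_map.items():
        anchor = by_name[rep]
        for dup in dups:
            joint = Node(length=anchor.length)
            parent = anchor.parent
            parent.children[parent.children.index(anchor)] = joint
            joint.parent = parent
            anchor.length = 0.0
            joint.add(anchor)
            joint.add(Node(dup, 0.0))
            anchor = joint.children[1]
    return tree


# --------------------------------------------------------------------------
# Newick

_NEEDS_QUOTE = re.compile(r"[\s(),:;'\[\]]")


def _quote(name: str) -> str:
    if name and not _NEEDS_QUOTE.search(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def write_newick(tree: Tree, supports: bool = True, precision: int = 5) -> str:
    """Serialize to Newick, supports as internal labels, fixed precision."""
    fmt = f"%.{precision}f"

    def rec(node: Node) -> str:
        if node.is_leaf:
            s = _quote(node.name)
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if supports and node.support is not None and node.parent is not None:
                s += f"{node.support:.3f}"
        if node.parent is not None:
            s += ":" + fmt % node.length
        return s

    return rec(tree.root) + ";"


def read_newick(source) -> Tree:
    """Parse Newick text or a file path into a :class:`Tree`.

    Internal node labels that parse as floats are kept as supports.  A
    bifurcating top node is collapsed into the trifurcation convention.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              preserve_underscores=True)

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            return Node(dnode.taxon.label if dnode.taxon else dnode.label,
                        dnode.edge.length)
        n = Node(length=dnode.edge.length)
        label = dnode.label
        if label is not None:
            try:
                n.support = float(label)
            except ValueError:
                n.name = label
        for c in dnode.child_nodes():
            n.add(convert(c))
        return n

    root = convert(dtree.seed_node)
    root.length = None
    if len(root.children) == 2:
        root = collapse_root_bifurcation(root)
    return Tree(root)
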