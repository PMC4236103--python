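"""Amino-acid substitutions reachable within one nucleotide change.

An *accessible* substitution is an amino-acid change obtainable by mutating
exactly one base of a codon in the reference coding sequence. Synonymous
changes and changes creating a stop codon are excluded: only genuine
amino-acid replacements count, and multiple mutational routes to the same
replacement at a site collapse to a single substitution.

Residue numbering follows the mature-protein convention used for the phage
φX174 coat protein F: the initiator methionine is cleaved after translation,
so with ``remove_initial_met=True`` residue 1 is the second translated codon.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

BASES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

# Standard genetic code (NCBI translation table 1); φX174 uses it.
# Single source of truth for the whole package.
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class SubstitutionKey(NamedTuple):
    """One amino-acid replacement: 1-based residue ``site``, ``aa_from`` → ``aa_to``."""

    site: int
    aa_from: str
    aa_to: str

    def validate(self) -> "SubstitutionKey":
        if self.site < 1:
            raise ValueError(f"site must be >= 1, got {self.site}")
        for aa, label in ((self.aa_from, "aa_from"), (self.aa_to, "aa_to")):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{label} {aa!r} is not a standard amino acid")
        if self.aa_from == self.aa_to:
            raise ValueError(f"aa_from and aa_to are both {self.aa_from!r}")
        return self


def _clean_codon(codon: str) -> str:
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in BASES for b in c):
        raise ValueError(f"not a valid codon: {codon!r}")
    return c


def clean_dna(seq: str) -> str:
    """Uppercase, map U→T, and reject characters outside {A,C,G,T}."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - set(BASES)
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    return s


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[_clean_codon(codon)]


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3) into amino acids, '*' for stops."""
    s = clean_dna(cds)
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    return "".join(GENETIC_CODE[s[i : i + 3]] for i in range(0, len(s), 3))


def single_nt_neighbors(codon: str) -> set[str]:
    """The 9 codons differing from ``codon`` at exactly one position."""
    c = _clean_codon(codon)
    return {
        c[:i] + b + c[i + 1 :]
        for i in range(3)
        for b in BASES
        if b != c[i]
    }


def accessible_aa_changes(codon: str) -> set[str]:
    """Amino acids reachable from ``codon`` by one base change.

    Excludes the codon's own amino acid (synonymous changes) and stop
    codons (nonsense changes). At most 9 amino acids can be returned.
    """
    c = _clean_codon(codon)
    own = GENETIC_CODE[c]
    if own == STOP:
        raise ValueError(f"codon {c} is a stop codon")
    return {
        aa
        for aa in (GENETIC_CODE[n] for n in single_nt_neighbors(c))
        if aa != own and aa != STOP
    }


def enumerate_accessible(cds: str, remove_initial_met: bool = True) -> set[SubstitutionKey]:
    """All substitutions accessible from ``cds`` within one DNA change.

    Parameters
    ----------
    cds
        Coding sequence; length divisible by 3 and no internal stop codon.
        A trailing stop codon is permitted and ignored.
    remove_initial_met
        When True (the coat-protein-F convention) the CDS must begin with
        ATG; that initiator codon is skipped and numbering starts at 1 on
        the following residue.
    """
    s = clean_dna(cds)
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons and GENETIC_CODE[codons[-1]] == STOP:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if GENETIC_CODE[c] == STOP:
            raise ValueError(f"internal stop codon {c} at codon {i + 1}")
    if remove_initial_met:
        if not codons or codons[0] != "ATG":
            raise ValueError("CDS must begin with ATG when remove_initial_met is set")
        codons = codons[1:]
    keys: set[SubstitutionKey] = set()
    for site, codon in enumerate(codons, start=1):
        aa_from = GENETIC_CODE[codon]
        for aa_to in accessible_aa_changes(codon):
            keys.add(SubstitutionKey(site, aa_from, aa_to))
    return keys


def enumerate_all(protein: str) -> set[SubstitutionKey]:
    """All 19·L possible single substitutions of an L-residue protein."""
    p = str(protein).upper()
    bad = set(p) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid amino-acid characters: {sorted(bad)}")
    return {
        SubstitutionKey(site, aa_from, aa_to)
        for site, aa_from in enumerate(p, start=1)
        for aa_to in AMINO_ACIDS
        if aa_to != aa_from
    }


def read_cds(path: str, gene: str | None = None, fmt: str | None = None) -> str:
    """Read a coding DNA sequence from FASTA or GenBank.

    For GenBank input with ``gene`` given, the CDS feature whose ``gene``
    qualifier matches is extracted; otherwise the first record's plain
    sequence is returned.
    """
    from Bio import SeqIO

    if fmt is None:
        fmt = "genbank" if str(path).lower().endswith((".gb", ".gbk", ".genbank")) else "fasta"
    record = next(SeqIO.parse(path, fmt))
    if fmt == "genbank" and gene is not None:
        for feat in record.features:
            if feat.type == "CDS" and gene in feat.qualifiers.get("gene", []):
                return clean_dna(str(feat.extract(record.seq)))
        raise ValueError(f"no CDS feature with gene {gene!r} in {path}")
    return clean_dna(str(record.seq))


def write_substitution_keys(keys: Iterable[SubstitutionKey], path: str) -> None:
    """Write substitution keys as TSV with columns site, aa.from, aa.to."""
    rows = sorted(keys)
    with open(path, "w") as fh:
        fh.write("site\taa.from\taa.to\n")
        for k in rows:
            fh.write(f"{k.site}\t{k.aa_from}\t{k.aa_to}\n")
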