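"""miRBase-style miRNA name handling.

Mature miRNA names follow the miRBase convention: an organism prefix
(``hsa`` for human), a family word (``miR``, ``let``, ``lin``), a family
number, an optional letter suffix for closely related sequences
(``miR-103a``), an optional dash-number when several loci encode the same
mature sequence (``miR-30c-2``), and an optional arm designator (``-5p`` /
``-3p``, or a trailing ``*`` marking the minor product of a hairpin).

Curated SNP-miRNA pair lists frequently carry generic names (``let-7``)
that predate the arm-specific delineation; :func:`expand_pairs` maps each
generic name onto every matching arm-specific name present on the
expression platform (``let-7`` -> ``let-7a-3p``, ``let-7a-5p``,
``let-7b-3p``, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = ["MirnaName", "parse_mirna_name", "format_mirna_name", "expand_pairs"]

#: family words recognised as the start of a miRNA name (case-insensitive)
_FAMILY_WORDS = {"mir", "let", "lin"}

_NUM_TOKEN = re.compile(r"^(\d+)([a-z]*)$", re.IGNORECASE)


@dataclass(frozen=True)
class MirnaName:
    """Parsed components of a mature miRNA name.

    ``prefix`` is the organism code (``hsa``) or ``None`` for a generic
    name; ``family_word`` keeps the original capitalisation (``miR``);
    ``arm`` is one of ``"5p"``, ``"3p"``, ``"star"`` or ``""``.
    """

    family_word: str
    number: int
    prefix: str | None = None
    variant: str = ""
    locus: int | None = None
    arm: str = ""

    @property
    def family(self) -> str:
        """Case-normalised family token, e.g. ``mir-143`` or ``let-7``."""
        return f"{self.family_word.lower()}-{self.number}"

    def matches(self, specific: "MirnaName") -> bool:
        """Whether ``specific`` is an admissible expansion of this name.

        The family token must match; a prefix, letter variant, locus or
        arm present in *this* (possibly generic) name must match exactly
        in ``specific``. Prefix comparison is case-insensitive.
        """
        if self.family != specific.family:
            return False
        if self.prefix is not None:
            if specific.prefix is None or self.prefix.lower() != specific.prefix.lower():
                return False
        if self.variant and self.variant != specific.variant:
            return False
        if self.locus is not None and self.locus != specific.locus:
            return False
        if self.arm and self.arm != specific.arm:
            return False
        return True

    def __str__(self) -> str:
        return format_mirna_name(self)


def parse_mirna_name(text: str) -> MirnaName:
    """Parse a miRBase-style name into its components.

    Raises ``ValueError`` for an unparseable token; callers handling
    curated lists should catch it and flag the record rather than abort.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty miRNA name")
    raw = text.strip()
    arm = ""
    if raw.endswith("*"):
        arm = "star"
        raw = raw[:-1]
    tokens = raw.split("-")
    if len(tokens) < 2:
        raise ValueError(f"unparseable miRNA name {text!r}: expected dash-separated tokens")

    prefix: str | None = None
    if tokens[0].lower() not in _FAMILY_WORDS:
        if not tokens[0].isalpha():
            raise ValueError(f"unparseable miRNA name {text!r}: bad organism prefix {tokens[0]!r}")
        prefix = tokens[0]
        tokens = tokens[1:]
    if not tokens or tokens[0].lower() not in _FAMILY_WORDS:
        raise ValueError(f"unparseable miRNA name {text!r}: unknown family word")
    family_word = tokens[0]
    tokens = tokens[1:]
    if not tokens:
        raise ValueError(f"unparseable miRNA name {text!r}: missing family number")
    m = _NUM_TOKEN.match(tokens[0])
    if m is None:
        raise ValueError(f"unparseable miRNA name {text!r}: bad number token {tokens[0]!r}")
    number = int(m.group(1))
    variant = m.group(2)
    tokens = tokens[1:]

    locus: int | None = None
    for i, tok in enumerate(tokens):
        low = tok.lower()
        if low in ("5p", "3p"):
            if i != len(tokens) - 1 or arm == "star":
                raise ValueError(f"unparseable miRNA name {text!r}: arm token not terminal")
            arm = low
        elif tok.isdigit():
            if locus is not None:
                raise ValueError(f"unparseable miRNA name {text!r}: repeated locus token")
            locus = int(tok)
        else:
            raise ValueError(f"unparseable miRNA name {text!r}: unexpected token {tok!r}")
    return MirnaName(
        family_word=family_word,
        number=number,
        prefix=prefix,
        variant=variant,
        locus=locus,
        arm=arm,
    )


def format_mirna_name(name: MirnaName) -> str:
    """Inverse of :func:`parse_mirna_name`; round-trips valid names."""
    parts = []
    if name.prefix is not None:
        parts.append(name.prefix)
    parts.append(name.family_word)
    num = f"{name.number}{name.variant}"
    parts.append(num)
    if name.locus is not None:
        parts.append(str(name.locus))
    out = "-".join(parts)
    if name.arm in ("5p", "3p"):
        out += f"-{name.arm}"
    elif name.arm == "star":
        out += "*"
    return out


def expand_pairs(pairs: pd.DataFrame, catalog: list[str] | pd.Index) -> pd.DataFrame:
    """Expand generic miRNA names in a SNP-miRNA pair list to the
    arm-specific names present on the expression platform.

    Parameters
    ----------
    pairs : DataFrame with columns ``snp_id``, ``gene_labels``, ``mirna_name``.
    catalog : iterable of platform miRNA names (strings).

    Returns
    -------
    DataFrame with columns ``snp_id``, ``gene_labels``, ``mirna_name``,
    ``source_name`` (the curated name the record came from) and
    ``matched`` (False when the curated name had no platform match or
    could not be parsed; such records are retained so the expression
    filter can drop and count them). Duplicate (snp_id, mirna_name)
    records are removed, keeping the first occurrence.
    """
    required = {"snp_id", "mirna_name"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pair list missing columns: {sorted(missing)}")
    if len(catalog) == 0:
        raise ValueError("platform catalog is empty")

    parsed_catalog: list[tuple[str, MirnaName]] = []
    for cname in catalog:
        try:
            parsed_catalog.append((str(cname), parse_mirna_name(str(cname))))
        except ValueError:
            continue  # non-standard platform rows cannot be expansion targets

    records = []
    for _, row in pairs.iterrows():
        source = str(row["mirna_name"])
        gene = row.get("gene_labels", "")
        try:
            query = parse_mirna_name(source)
        except ValueError:
            records.append(
                {"snp_id": row["snp_id"], "gene_labels": gene,
                 "mirna_name": source, "source_name": source, "matched": False}
            )
            continue
        hits = [cname for cname, cparsed in parsed_catalog if query.matches(cparsed)]
        if not hits:
            records.append(
                {"snp_id": row["snp_id"], "gene_labels": gene,
                 "mirna_name": source, "source_name": source, "matched": False}
            )
        else:
            for hit in hits:
                records.append(
                    {"snp_id": row["snp_id"], "gene_labels": gene,
                     "mirna_name": hit, "source_name": source, "matched": True}
                )
    out = pd.DataFrame.from_records(
        records, columns=["snp_id", "gene_labels", "mirna_name", "source_name", "matched"]
    )
    out = out.drop_duplicates(subset=["snp_id", "mirna_name"], keep="first")
    return out.reset_index(drop=True)
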