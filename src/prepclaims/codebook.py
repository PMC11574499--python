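"""Code lists and code-matching semantics for the PrEP indication algorithm.

The algorithm hinges on a small dictionary of ICD-9 diagnosis codes, CPT
procedure codes and GPI (generic product identifier) drug codes: HIV markers,
AIDS-defining opportunistic infections, chronic hepatitis B, needle-stick /
prophylaxis codes, and the antiretroviral / hepatitis-B drug classes. This
module owns that dictionary (the :class:`Codebook`), the normalization rules
that make dotted, undotted and un-zero-padded spellings of the same ICD-9
code compare equal, and the wildcard semantics used by entries such as
``130.*`` (a three-digit category plus all of its subcodes) and ``1210xxx``
(a GPI class prefix).

ICD-9 canonical form
--------------------
An ICD-9 code is stored as ``CATEGORY[.SUBCODE]`` where the category is the
zero-padded three-digit rubric (``070``), a V-code (``V07``) or an E-code
(``E920``), and the subcode — when present — follows a literal dot. Thus
``070.22``, ``70.22`` and ``07022`` all normalize to ``070.22``. Keeping the
dot in the canonical form makes category matching unambiguous: ``130.*``
matches ``130`` and anything beginning ``130.``, and can never swallow an
unrelated four-digit string.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "CodeSystem",
    "CodePattern",
    "Codebook",
    "CodebookError",
    "normalize_code",
    "match_code",
    "load_codebook",
    "CATEGORIES",
    "DRUG_CATEGORIES",
]


class CodebookError(ValueError):
    """Raised for malformed codebooks or invalid codes."""


class CodeSystem(str, enum.Enum):
    ICD9_DX = "ICD9_DX"
    CPT = "CPT"
    GPI = "GPI"


#: Every category the algorithm knows about, in a fixed canonical order.
CATEGORIES: tuple[str, ...] = (
    "HIV_DX",
    "OI_DX",
    "CHB_DX",
    "NEEDLESTICK",
    "PROPHYLAXIS",
    "TDF_FTC",
    "FTC",
    "TDF",
    "ARV_OTHER",
    "HBV_AGENT",
    "HIGH_RISK_SEX",
    "PREVENTION_COUNSELING",
)

#: Drug-class categories (GPI patterns); precedence order for categorize_drug.
DRUG_CATEGORIES: tuple[str, ...] = ("TDF_FTC", "FTC", "TDF", "ARV_OTHER", "HBV_AGENT")

_CATEGORY_SYSTEM: dict[str, CodeSystem] = {
    "HIV_DX": CodeSystem.ICD9_DX,
    "OI_DX": CodeSystem.ICD9_DX,
    "CHB_DX": CodeSystem.ICD9_DX,
    "NEEDLESTICK": CodeSystem.ICD9_DX,
    "PROPHYLAXIS": CodeSystem.ICD9_DX,
    "HIGH_RISK_SEX": CodeSystem.ICD9_DX,
    "TDF_FTC": CodeSystem.GPI,
    "FTC": CodeSystem.GPI,
    "TDF": CodeSystem.GPI,
    "ARV_OTHER": CodeSystem.GPI,
    "HBV_AGENT": CodeSystem.GPI,
    "PREVENTION_COUNSELING": CodeSystem.CPT,
}

_WILDCARD_CHARS = frozenset("*Xx")


def _split_icd9(stripped: str, had_dot: bool, dot_index: int) -> tuple[str, str]:
    """Split a dot-stripped, upper-cased ICD-9 string into (category, subcode)."""
    if had_dot:
        cat, sub = stripped[:dot_index], stripped[dot_index:]
    elif stripped.startswith("E"):
        cat, sub = stripped[:4], stripped[4:]
    elif stripped.startswith("V"):
        cat, sub = stripped[:3], stripped[3:]
    else:
        if len(stripped) <= 3:
            cat, sub = stripped, ""
        else:
            # Undotted numeric codes are assumed zero-padded (standard claims
            # convention), so the first three characters are the rubric.
            cat, sub = stripped[:3], stripped[3:]
    # Zero-pad the numeric part of the category: 42 -> 042, V8 -> V08, E92 -> E920.
    if cat.startswith("E"):
        cat = "E" + cat[1:].zfill(3)
    elif cat.startswith("V"):
        cat = "V" + cat[1:].zfill(2)
    else:
        cat = cat.zfill(3)
    return cat, sub


def normalize_code(code: str, system: CodeSystem) -> str:
    """Return the canonical spelling of *code* under *system*.

    ICD-9 codes come back as zero-padded ``CATEGORY[.SUBCODE]``; GPI and CPT
    codes have dots and whitespace removed. Raises :class:`CodebookError` on
    an empty code.
    """
    if not code or not str(code).strip():
        raise CodebookError("empty code")
    raw = "".join(str(code).split()).upper()
    if system is not CodeSystem.ICD9_DX:
        return raw.replace(".", "")
    dot_index = raw.find(".")
    had_dot = dot_index >= 0
    stripped = raw.replace(".", "")
    if had_dot and dot_index > len(stripped):
        dot_index = len(stripped)
    cat, sub = _split_icd9(stripped, had_dot, dot_index)
    return f"{cat}.{sub}" if sub else cat


@dataclass(frozen=True)
class CodePattern:
    """A code pattern as printed in the algorithm's code table.

    ``raw_pattern`` keeps the original spelling (``"130.*"``, ``"1210xxx"``);
    wildcard markers (``*``, ``X``, ``x``) may appear only as a trailing run.
    """

    raw_pattern: str
    system: CodeSystem

    def __post_init__(self) -> None:
        if not self.raw_pattern or not self.raw_pattern.strip():
            raise CodebookError("empty pattern")
        body = self.raw_pattern.rstrip("".join(_WILDCARD_CHARS))
        tail = self.raw_pattern[len(body):]
        if any(c in _WILDCARD_CHARS for c in body):
            raise CodebookError(
                f"wildcard markers must be a trailing run: {self.raw_pattern!r}"
            )
        if not body.rstrip("."):
            raise CodebookError(f"pattern has no fixed prefix: {self.raw_pattern!r}")
        object.__setattr__(self, "_tail", tail)

    @property
    def is_wildcard(self) -> bool:
        return bool(self._tail)  # type: ignore[attr-defined]

    @property
    def prefix(self) -> str:
        """Normalized fixed part of the pattern."""
        body = self.raw_pattern.rstrip("".join(_WILDCARD_CHARS)).rstrip(".")
        return normalize_code(body, self.system)

    @property
    def normalized(self) -> str:
        """Canonical form for exact patterns (same as prefix for wildcards)."""
        return self.prefix


def match_code(code: str, pattern: CodePattern) -> bool:
    """True iff *code* (already in canonical form) matches *pattern*.

    Exact patterns require equality of canonical forms. Wildcard patterns are
    prefix matches: for ICD-9, the code must be the pattern's category itself
    or one of its dotted subcodes; for GPI/CPT, a plain string-prefix match.
    A code from a different code system never matches (returns False, never
    raises).
    """
    if not code:
        return False
    code = str(code)
    if pattern.system is CodeSystem.ICD9_DX:
        # An ICD-9 canonical form is letters/digits with at most one dot; a
        # GPI/CPT code handed in by mistake simply fails the comparisons.
        if pattern.is_wildcard:
            p = pattern.prefix
            return code == p or code.startswith(p + ".")
        return code == pattern.normalized
    # GPI / CPT
    if "." in code:
        return False
    if pattern.is_wildcard:
        return code.startswith(pattern.prefix)
    return code == pattern.normalized


def _p(raw: str, system: CodeSystem) -> CodePattern:
    return CodePattern(raw, system)


def _default_mapping() -> dict[str, list[CodePattern]]:
    icd, gpi, cpt = CodeSystem.ICD9_DX, CodeSystem.GPI, CodeSystem.CPT
    return {
        "HIV_DX": [_p("042", icd), _p("V08", icd), _p("079.53", icd)],
        "OI_DX": [
            _p("112.84", icd),
            _p("112.4", icd),
            _p("130.*", icd),
            _p("114.X", icd),
            _p("117.5", icd),
            _p("007.4", icd),
            _p("078.5", icd),
            _p("176.X", icd),
            _p("031.2", icd),
            _p("031.0", icd),
            _p("136.3", icd),
        ],
        "CHB_DX": [
            _p("70.22", icd),
            _p("70.23", icd),
            _p("70.32", icd),
            _p("70.33", icd),
        ],
        "NEEDLESTICK": [_p("E920.5", icd)],
        "PROPHYLAXIS": [_p("V078", icd), _p("V079", icd)],
        "TDF_FTC": [_p("1210990230", gpi)],
        "FTC": [_p("121060300", gpi)],
        "TDF": [_p("1210857010", gpi)],
        "ARV_OTHER": [_p("1210xxx", gpi)],
        "HBV_AGENT": [_p("123520xxx", gpi)],
        "HIGH_RISK_SEX": [_p("V69.2", icd)],
        "PREVENTION_COUNSELING": [_p("99401", cpt), _p("99402", cpt), _p("99403", cpt)],
    }


@dataclass
class Codebook:
    """Category -> code-pattern lists, with matching helpers.

    The default codebook reproduces the published algorithm's code table; a
    config file can override or extend individual categories (see
    :func:`load_codebook`). ``pep_extension`` holds optional exposure-contact
    ICD-9 codes used only by the opt-in PEP duration heuristic.
    """

    patterns: dict[str, list[CodePattern]] = field(default_factory=_default_mapping)
    pep_extension: list[CodePattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            self.patterns.setdefault(cat, [])
        unknown = set(self.patterns) - set(CATEGORIES)
        if unknown:
            raise CodebookError(f"unknown categories: {sorted(unknown)}")
        seen: dict[str, str] = {}
        for cat in DRUG_CATEGORIES:
            for pat in self.patterns[cat]:
                key = pat.raw_pattern
                if key in seen and seen[key] != cat:
                    raise CodebookError(
                        f"GPI pattern {key!r} assigned to both {seen[key]} and {cat}"
                    )
                seen[key] = cat

    # -- event / drug categorization -------------------------------------

    def categorize_event(self, system: CodeSystem, code: str) -> set[str]:
        """All categories whose pattern lists match the (normalized) code."""
        norm = normalize_code(code, system)
        out: set[str] = set()
        for cat in CATEGORIES:
            if _CATEGORY_SYSTEM[cat] is not system:
                continue
            if any(match_code(norm, pat) for pat in self.patterns[cat]):
                out.add(cat)
        return out

    def categorize_drug(self, gpi: str) -> str:
        """Drug class for a GPI code: one of the drug categories or ``OTHER``.

        Exact (fully specified) patterns take precedence over class-prefix
        wildcards, so the specific TDF/FTC, FTC and TDF products are never
        absorbed into the generic antiretroviral class.
        """
        norm = normalize_code(gpi, CodeSystem.GPI)
        for wildcard_pass in (False, True):
            for cat in DRUG_CATEGORIES:
                for pat in self.patterns[cat]:
                    if pat.is_wildcard is wildcard_pass and match_code(norm, pat):
                        return cat
        return "OTHER"

    def is_pep_extension(self, system: CodeSystem, code: str) -> bool:
        norm = normalize_code(code, system)
        return any(
            pat.system is system and match_code(norm, pat)
            for pat in self.pep_extension
        )

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {cat: [p.raw_pattern for p in self.patterns[cat]] for cat in CATEGORIES}
        if self.pep_extension:
            out["PEP_EXTENSION"] = [p.raw_pattern for p in self.pep_extension]
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "Codebook":
        if not isinstance(data, dict):
            raise CodebookError("codebook config must be a mapping")
        base = _default_mapping()
        pep_ext: list[CodePattern] = []
        for cat, codes in data.items():
            if codes is None:
                codes = []
            if not isinstance(codes, list) or not all(isinstance(c, str) for c in codes):
                raise CodebookError(f"category {cat!r} must map to a list of strings")
            if cat == "PEP_EXTENSION":
                pep_ext = [_p(c, CodeSystem.ICD9_DX) for c in codes]
                continue
            if cat not in CATEGORIES:
                raise CodebookError(f"unknown category {cat!r}")
            base[cat] = [_p(c, _CATEGORY_SYSTEM[cat]) for c in codes]
        return cls(patterns=base, pep_extension=pep_ext)


def load_codebook(path: str | Path | None = None) -> Codebook:
    """Load a codebook config file, or the embedded defaults when *path* is None.

    The file is a flat YAML map of category name -> list of pattern strings;
    categories not mentioned keep their defaults; unknown category names are
    rejected so that typos surface.
    """
    if path is None:
        return Codebook()
    p = Path(path)
    if not p.exists():
        raise CodebookError(f"codebook file not found: {p}")
    try:
        data = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise CodebookError(f"malformed codebook file {p}: {exc}") from exc
    if data is None:
        return Codebook()
    return Codebook.from_dict(data)
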