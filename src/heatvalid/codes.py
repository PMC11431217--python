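"""ICD-10 code normalization and case-finding code sets.

A case-finding (coding) algorithm is a set of ICD-10 code *prefixes*: an
encounter is algorithm-positive when at least one of its assigned codes, in
any diagnostic field, starts with an include prefix.  Prefix semantics let a
three-character category such as ``N17`` (acute kidney injury) capture all of
its more specific children (``N170``–``N179``), which is how administrative
records mix coding specificity in practice.

The bundled default is the acute-heat-illness (AHI) set: direct heat-effect
codes (``X30``, ``X32``, ``T670``–``T679``) plus "expanded" codes for the
downstream consequences of heat illness (volume depletion, acute kidney
injury, hyperthermic fever, rhabdomyolysis, electrolyte disorders, syncope).
``W92`` (excessive heat of human-made origin, e.g. saunas or industrial heat)
is deliberately left out of the includes; it is recorded in ``excludes`` for
documentation, but its presence on a chart does *not* veto other matching
codes — it simply never triggers a match itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "CodeValidationError",
    "CodeSet",
    "normalize_code",
    "build_ahi_codeset",
    "code_matches",
    "encounter_is_algorithm_positive",
    "load_codeset",
    "save_codeset",
    "resolve_codeset",
]

# letter + two digits + up to four more alphanumerics (ICD-10 shape, dotless)
_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]{0,4}$")


class CodeValidationError(ValueError):
    """A string cannot be interpreted as an ICD-10 code, or a code set is inconsistent."""


def normalize_code(raw: str) -> str:
    """Canonicalize an ICD-10 code: uppercase, no dot, no whitespace.

    >>> normalize_code("T67.0")
    'T670'
    >>> normalize_code("n17")
    'N17'

    Raises :class:`CodeValidationError` for empty or malformed input.
    Idempotent: ``normalize_code(normalize_code(x)) == normalize_code(x)``.
    """
    if raw is None:
        raise CodeValidationError("ICD-10 code is None")
    cleaned = "".join(str(raw).split()).replace(".", "").upper()
    if not cleaned:
        raise CodeValidationError(f"empty ICD-10 code: {raw!r}")
    if not _CODE_RE.match(cleaned):
        raise CodeValidationError(f"malformed ICD-10 code: {raw!r}")
    return cleaned


@dataclass(frozen=True)
class CodeSet:
    """A named case-finding algorithm: include prefixes plus documented exclusions.

    ``includes`` and ``excludes`` are normalized on construction and must be
    disjoint.  ``excludes`` is documentation only — see :func:`code_matches`.
    """

    name: str
    includes: frozenset = frozenset()
    excludes: frozenset = frozenset()
    _prefixes: tuple = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        inc = frozenset(normalize_code(c) for c in self.includes)
        exc = frozenset(normalize_code(c) for c in self.excludes)
        if inc & exc:
            raise CodeValidationError(
                f"code set {self.name!r}: includes and excludes overlap: {sorted(inc & exc)}"
            )
        object.__setattr__(self, "includes", inc)
        object.__setattr__(self, "excludes", exc)
        object.__setattr__(self, "_prefixes", tuple(sorted(inc)))


#: Table of include prefixes for the AHI algorithm.  Category-level entries
#: (N17, E87, R55) capture all child codes by the prefix rule; E875 is kept
#: verbatim even though E87 already covers it.
AHI_INCLUDES = (
    "X30",   # exposure to excessive natural heat
    "X32",   # exposure to sunlight
    "T670",  # heat stroke and sunstroke
    "T671",  # heat syncope
    "T672",  # heat cramp
    "T673",  # heat exhaustion, anhidrotic
    "T674",  # heat exhaustion due to salt depletion
    "T675",  # heat exhaustion, unspecified
    "T676",  # heat fatigue, transient
    "T677",  # heat edema
    "T678",  # other effects of heat and light
    "T679",  # effect of heat and light, unspecified
    "E860",  # volume depletion
    "E868",
    "N17",   # acute kidney injury
    "R508",  # other specified fever (hyperthermia)
    "R509",  # fever, unspecified
    "M628",  # rhabdomyolysis
    "T296",
    "G210",
    "E87",   # sodium disorders
    "E875",  # potassium disorders / hyperkalemia
    "R55",   # syncope and collapse
)

AHI_EXCLUDES = ("W92",)  # excessive heat of human-made origin


def build_ahi_codeset() -> CodeSet:
    """Return the acute-heat-illness case-finding algorithm (23 include prefixes)."""
    return CodeSet(name="ahi", includes=frozenset(AHI_INCLUDES), excludes=frozenset(AHI_EXCLUDES))


def code_matches(codeset: CodeSet, code: str) -> bool:
    """True iff some include prefix of ``codeset`` is a prefix of ``code``.

    ``code`` must already be normalized.  Excludes never veto: a chart code
    equal to an exclude simply fails to match.
    """
    return code.startswith(codeset._prefixes) if codeset._prefixes else False


def encounter_is_algorithm_positive(codeset: CodeSet, codes: Iterable[str]) -> bool:
    """True iff at least one assigned code matches, in any diagnostic field.

    An empty code list is negative.
    """
    prefixes = codeset._prefixes
    if not prefixes:
        return False
    return any(c.startswith(prefixes) for c in codes)


def load_codeset(path: str | Path) -> CodeSet:
    """Read a code-set registry file (YAML: name, includes, excludes)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "name" not in doc or "includes" not in doc:
        raise CodeValidationError(f"code-set file {path}: expected keys name, includes[, excludes]")
    return CodeSet(
        name=str(doc["name"]),
        includes=frozenset(doc["includes"] or ()),
        excludes=frozenset(doc.get("excludes") or ()),
    )


def save_codeset(codeset: CodeSet, path: str | Path) -> None:
    """Write a code set to a YAML registry file."""
    doc = {
        "name": codeset.name,
        "includes": sorted(codeset.includes),
        "excludes": sorted(codeset.excludes),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def resolve_codeset(spec: str) -> CodeSet:
    """Resolve a CLI-style code-set reference: ``builtin:ahi`` or a file path."""
    if spec == "builtin:ahi":
        return build_ahi_codeset()
    if spec.startswith("builtin:"):
        raise CodeValidationError(f"unknown builtin code set: {spec}")
    return load_codeset(spec)
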