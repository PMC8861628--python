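"""EMR field registry.

A record carries two kinds of text fields: static fields that describe the
patient across their whole history, and per-consultation fields filled in
during a visit.  Every bag-of-words feature is prefixed with a short field
code so that, e.g., a disease mentioned in a patient's personal history and
the same disease in their family history remain distinct features.
"""

from __future__ import annotations

# Per-consultation free-text fields.
CONSULTATION_FIELDS: tuple[str, ...] = (
    "reasons",
    "observations",
    "symptoms",
    "diagnoses",
    "drugs",
    "care_procedures",
    "prescription_reasons",
)

# Patient-level (static) free-text fields.
STATIC_FIELDS: tuple[str, ...] = (
    "personal_history",
    "family_history",
    "past_problems",
    "allergies",
    "environmental_factors",
    "current_problems",
)

ALL_FIELDS: tuple[str, ...] = CONSULTATION_FIELDS + STATIC_FIELDS

# Short prefixes used in bag-of-words feature names ("obs:phlebite").
FIELD_PREFIXES: dict[str, str] = {
    "reasons": "rc",
    "observations": "obs",
    "symptoms": "sym",
    "diagnoses": "dx",
    "drugs": "rx",
    "care_procedures": "proc",
    "prescription_reasons": "presc",
    "personal_history": "ph",
    "family_history": "fh",
    "past_problems": "pp",
    "allergies": "alg",
    "environmental_factors": "env",
    "current_problems": "cp",
}

# Fields excluded by the record-centred ("s*") extraction scope: they carry
# information about relatives or resolved/episodic complaints rather than the
# patient's own current record.
S_STAR_EXCLUDED: frozenset[str] = frozenset(
    {"family_history", "past_problems", "symptoms"}
)

S_STAR_SCOPE: tuple[str, ...] = tuple(
    f for f in ALL_FIELDS if f not in S_STAR_EXCLUDED
)
FULL_SCOPE: tuple[str, ...] = ALL_FIELDS


def validate_scope(scope) -> tuple[str, ...]:
    """Return *scope* as a tuple, raising on unknown field names."""
    scope = tuple(scope)
    unknown = [f for f in scope if f not in ALL_FIELDS]
    if unknown:
        raise ValueError(f"unknown EMR field(s): {unknown}")
    return scope
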