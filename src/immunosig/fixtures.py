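"""Packaged reference signature tables (see ``data/fixture_notes.md``)."""

from __future__ import annotations

from importlib import resources

from .signature_selection import PeptideSet

REFERENCE_SIGNATURES = ("diagnostic_lupus", "behavior_diagnostic", "predictive_lupus")

#: Rows whose printed cross-membership marks contradict the tables' own
#: member lists; consistency checks must skip these (data/fixture_notes.md).
KNOWN_FLAG_INCONSISTENCIES = {
    ("behavior_diagnostic", "LAFAWKPDPWQSLVTKFGSC"),
    ("predictive_lupus", "KIWAMRKPRYQYWNQPAGSC"),
}


def load_reference_signature(name: str) -> PeptideSet:
    """Load one of the published intersected signatures.

    ``name`` is one of ``diagnostic_lupus`` (58 peptides),
    ``behavior_diagnostic`` (39) or ``predictive_lupus`` (18). Peptide ids
    are the sequences themselves.
    """
    from .array_io import read_signature_table

    if name not in REFERENCE_SIGNATURES:
        raise ValueError(f"unknown reference signature {name!r}; "
                         f"choose from {REFERENCE_SIGNATURES}")
    path = resources.files("immunosig").joinpath("data", f"{name}.tsv")
    with resources.as_file(path) as p:
        pset = read_signature_table(p, name=name)
    if "sequence" not in pset.members.columns:
        pset.members.insert(0, "sequence", pset.members.index)
    return pset
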