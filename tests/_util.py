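"""Small shared helpers for the suite."""

from sbpkb.sbol_model import CORE, KnowledgeGraph


def subject_names(kg: KnowledgeGraph, subjects) -> set[str]:
    """Map part-subject URIs to their sbolcore:name literal values."""
    return {str(kg.graph.value(s, CORE.name)) for s in subjects}


def result_names(kg: KnowledgeGraph, result) -> set[str]:
    return subject_names(kg, result.subjects)
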