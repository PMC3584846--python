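"""File readers/writers: annotations, models, predictions, OBO export.

Annotation inputs are either GAF 2.x (DB object id, GO id, evidence code,
aspect columns) or a plain two-column TSV (protein, term).  Annotations
carried by computational/electronic evidence codes are excluded by default
so that models are assessed against experimentally supported labels; the
code list is fully overridable.

Trained models serialize to JSON: training ids, candidate label term sets
and (example, candidate, α) triples — enough to reconstruct the
compatibility function exactly, without the training kernel.
"""

from __future__ import annotations

import json
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .labels import LabelSpace, StructuredLabel
from .ontology import NAMESPACE_NAMES, GeneOntology
from .ssvm import DualModel

logger = logging.getLogger(__name__)

#: evidence codes treated as "predicted through computational means"
DEFAULT_EVIDENCE_EXCLUSIONS = frozenset(
    {"IEA", "ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA"}
)

KNOWN_EVIDENCE_CODES = DEFAULT_EVIDENCE_EXCLUSIONS | {
    "EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI",
    "HEP", "TAS", "NAS", "IC", "ND",
}


def _iter_annotation_rows(path, fmt: str):
    """Yield (protein, term, evidence) rows from a GAF or 2-column TSV."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            parts = line.split("\t")
            if fmt == "gaf":
                if len(parts) < 7:
                    raise ParseError(
                        f"{path}:{lineno}: GAF row has {len(parts)} columns"
                    )
                yield parts[1], parts[4], parts[6]
            elif fmt == "tsv":
                if len(parts) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                evidence = parts[2] if len(parts) > 2 else None
                yield parts[0], parts[1], evidence
            else:
                raise ValidationError(f"unknown annotation format {fmt!r}")


def load_annotations(
    path,
    go: GeneOntology,
    fmt: str = "tsv",
    exclusions: Iterable[str] = DEFAULT_EVIDENCE_EXCLUSIONS,
    namespace: str | None = None,
) -> dict[str, StructuredLabel]:
    """Load per-protein structured labels from an annotation file.

    Rows with excluded evidence codes are dropped; per protein the
    surviving terms are unioned and ancestor-closed.  Unknown GO terms are
    logged and skipped; proteins left with no terms are omitted.  When
    ``namespace`` is given, terms of other namespaces are ignored.
    """
    exclusions = frozenset(exclusions)
    terms_of: dict[str, set[str]] = {}
    skipped_terms = 0
    for protein, term, evidence in _iter_annotation_rows(path, fmt):
        if evidence:
            if evidence not in KNOWN_EVIDENCE_CODES:
                logger.warning("unknown evidence code %r", evidence)
            if evidence in exclusions:
                continue
        if term not in go:
            skipped_terms += 1
            logger.info("unknown GO term %r skipped", term)
            continue
        if namespace is not None and go.namespace_of[term] != namespace:
            continue
        terms_of.setdefault(protein, set()).add(term)
    if skipped_terms:
        logger.info("load_annotations: %d rows with unknown terms skipped",
                    skipped_terms)
    out: dict[str, StructuredLabel] = {}
    for protein, terms in terms_of.items():
        if terms:
            out[protein] = StructuredLabel.from_terms(go, terms)
    return out


def write_annotations_tsv(
    labels: Mapping[str, StructuredLabel], path
) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tterm\n")
        for protein in sorted(labels):
            for term in sorted(labels[protein].terms):
                fh.write(f"{protein}\t{term}\n")


def write_predictions_tsv(
    predictions: Mapping[str, StructuredLabel], path
) -> None:
    write_annotations_tsv(predictions, path)


def write_obo(go: GeneOntology, path) -> None:
    """Write the ontology as a minimal OBO 1.2 file (is_a edges only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: structgo-export\n")
        for term in sorted(go.namespace_of):
            ns = go.namespace_of[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            fh.write(f"namespace: {NAMESPACE_NAMES.get(ns, ns)}\n")
            for parent in sorted(go.parents_of[term]):
                fh.write(f"is_a: {parent} ! {parent}\n")


# -- model serialization -----------------------------------------------------

MODEL_FORMAT = "structgo-dual-model"


def model_to_dict(model: DualModel) -> dict:
    return {
        "format": MODEL_FORMAT,
        "version": 1,
        "vocabulary": list(model.space.vocabulary),
        "train_ids": list(model.train_ids),
        "train_labels": [sorted(y.terms) for y in model.labels],
        "candidates": [sorted(c.terms) for c in model.space.candidates],
        "constraints": [
            [int(i), int(s), float(a)]
            for (i, s), a in zip(model.constraints, model.alpha)
        ],
        "c_over_n": model.c_over_n,
        "tolerance": model.tolerance,
        "objective_trace": [float(v) for v in model.objective_trace],
    }


def model_from_dict(data: Mapping) -> DualModel:
    if data.get("format") != MODEL_FORMAT:
        raise ValidationError("not a serialized structgo model")
    vocab = tuple(data["vocabulary"])
    space = LabelSpace(
        [StructuredLabel(t, vocab) for t in data["candidates"]]
    )
    labels = tuple(StructuredLabel(t, vocab) for t in data["train_labels"])
    constraints = [(int(i), int(s)) for i, s, _ in data["constraints"]]
    alpha = np.array([a for _, _, a in data["constraints"]], dtype=float)
    return DualModel(
        train_ids=tuple(data["train_ids"]),
        labels=labels,
        space=space,
        constraints=constraints,
        alpha=alpha,
        c_over_n=float(data["c_over_n"]),
        objective_trace=[float(v) for v in data.get("objective_trace", [])],
        tolerance=float(data.get("tolerance", 1e-4)),
    )


def save_model(model: DualModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> DualModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


# -- misc tables -------------------------------------------------------------


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="protein")


def read_scores_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def write_folds_tsv(folds: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tfold\n")
        for protein in sorted(folds):
            fh.write(f"{protein}\t{folds[protein]}\n")


def read_clusters_tsv(path) -> dict[str, str]:
    """Read a protein → cluster-id table (2 columns)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def read_identity_tsv(path) -> list[tuple[str, str, float]]:
    """Read pairwise identities (protein, protein, fraction in [0, 1])."""
    out: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                ident = float(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric identity {parts[2]!r}"
                ) from None
            out.append((parts[0], parts[1], ident))
    return out
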