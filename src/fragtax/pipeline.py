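"""Batch classification: apply one named method to a set of fragments.

This is the glue between the per-fragment classifier functions and the
file-level command line: it groups BLAST hits by query, reuses NB scores
across methods where possible and returns predictions in input order.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from . import classifiers as clf
from .classifiers import BlastHit, ClassifierParams, Prediction
from .composition import FrequencyProfile, NBModel
from .taxonomy import TaxonomyTree

COMPOSITION_METHODS = ("nb", "enb", "nn")
HOMOLOGY_METHODS = ("blast", "lca", "clca")
HYBRID_METHODS = ("blast+nb", "blast+enb", "lca+nb", "lca+enb")
METHODS = COMPOSITION_METHODS + HOMOLOGY_METHODS + ("nbbl",) + HYBRID_METHODS


def group_hits_by_query(hits: Sequence[BlastHit]) -> dict[str, list[BlastHit]]:
    out: dict[str, list[BlastHit]] = {}
    for h in hits:
        out.setdefault(h.query_id, []).append(h)
    return out


def classify_fragments(
    method: str,
    taxonomy: TaxonomyTree,
    fragments: Sequence[tuple[str, str]],
    models: Sequence[NBModel] | None = None,
    hits_by_query: Mapping[str, Sequence[BlastHit]] | None = None,
    nn_profiles: Mapping[str, FrequencyProfile] | None = None,
    params: ClassifierParams = clf.DEFAULT_PARAMS,
) -> list[Prediction]:
    """Classify (fragment_id, sequence) pairs with one named method.

    Methods: nb, enb, nn, blast, lca, clca, nbbl, and the four consensus
    hybrids blast+nb, blast+enb, lca+nb, lca+enb.  Composition methods
    need ``models`` (``nn_profiles`` for nn); homology methods need
    ``hits_by_query``; hybrids and nbbl need both.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    needs_models = method in ("nb", "enb", "nbbl") or method in HYBRID_METHODS
    needs_hits = method in HOMOLOGY_METHODS or method == "nbbl" or method in HYBRID_METHODS
    if needs_models and not models:
        raise ValueError(f"method {method!r} requires NB genome models")
    if method == "nn" and not nn_profiles:
        raise ValueError("method 'nn' requires training frequency profiles")
    if needs_hits and hits_by_query is None:
        raise ValueError(f"method {method!r} requires a BLAST hit table")

    predictions: list[Prediction] = []
    for fid, seq in fragments:
        hits = list(hits_by_query.get(fid, ())) if hits_by_query is not None else []
        if method == "nb":
            pred = clf.nb_classify(models, taxonomy, fid, seq)
        elif method == "enb":
            pred = clf.epsilon_nb_classify(
                models, taxonomy, fid, seq, epsilon=params.epsilon
            )
        elif method == "nn":
            pred = clf.nn_classify(nn_profiles, taxonomy, fid, seq)
        elif method == "blast":
            pred = clf.blast_best_hit_classify(
                hits, taxonomy, fid, evalue_max=params.evalue_max
            )
        elif method == "lca":
            pred = clf.lca_classify(
                hits, taxonomy, fid,
                evalue_max=params.evalue_max, p=params.lca_percent,
            )
        elif method == "clca":
            pred = clf.conservative_lca_classify(
                hits, taxonomy, fid, evalue_max=params.conservative_evalue_max
            )
        elif method == "nbbl":
            pred = clf.nbbl_classify(models, taxonomy, hits, fid, seq, params=params)
        else:  # consensus hybrids
            homology, composition = method.split("+")
            if homology == "blast":
                h_pred = clf.blast_best_hit_classify(
                    hits, taxonomy, fid, evalue_max=params.evalue_max
                )
            else:
                h_pred = clf.lca_classify(
                    hits, taxonomy, fid,
                    evalue_max=params.evalue_max, p=params.lca_percent,
                )
            if composition == "nb":
                c_pred = clf.nb_classify(models, taxonomy, fid, seq)
            else:
                c_pred = clf.epsilon_nb_classify(
                    models, taxonomy, fid, seq, epsilon=params.epsilon
                )
            pred = clf.consensus_classify(h_pred, c_pred)
        predictions.append(pred)
    return predictions
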