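"""Species- and age-specific divergence set algebra (hiDE / ciDE).

A gene is *species-specific* in a cell type when it is called DE with
concordant sign against both other species; it is *infant-specific*
(hiDE for human focus, ciDE for chimpanzee) when that call in infants is
not matched, same cell type and same direction, in adults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import pandas as pd

from .de import DESet, call_de
from .stats import enrich

__all__ = [
    "AgeSplitSets",
    "species_specific_de",
    "age_specific_sets",
    "upset_counts",
    "jaccard",
    "consistency_fraction",
    "flag_confounders",
]


def species_specific_de(
    calls_vs_b: pd.DataFrame,
    calls_vs_c: pd.DataFrame,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    mode: str = "both_contrasts",
) -> tuple[DESet, DESet]:
    """Focal-species gains and losses versus both other species.

    Default ``both_contrasts`` mode: a gain must pass the calling rule as
    a gain in focal-vs-B *and* focal-vs-C (sign conflicts drop the gene);
    ``one_vs_rest`` mode takes ``calls_vs_b`` as a pooled-rest contrast
    and applies the calling rule once.
    """
    gain_b, loss_b = call_de(calls_vs_b, lfc_threshold, fdr_threshold)
    if mode == "one_vs_rest":
        return gain_b, loss_b
    if mode != "both_contrasts":
        raise ValueError(f"unknown mode {mode!r}")
    gain_c, loss_c = call_de(calls_vs_c, lfc_threshold, fdr_threshold)
    for a, b in ((gain_b, gain_c), (loss_b, loss_c)):
        if (a.cell_type, a.species_focus, a.age_group) != (
            b.cell_type, b.species_focus, b.age_group
        ):
            raise ValueError(
                "contrast tables disagree on focal species, age group or cell type: "
                f"{(a.species_focus, a.age_group, a.cell_type)} vs "
                f"{(b.species_focus, b.age_group, b.cell_type)}"
            )
    return (
        DESet(gain_b.species_focus, gain_b.age_group, gain_b.cell_type, "gain",
              gain_b.genes & gain_c.genes),
        DESet(loss_b.species_focus, loss_b.age_group, loss_b.cell_type, "loss",
              loss_b.genes & loss_c.genes),
    )


@dataclass
class AgeSplitSets:
    """Infant-specific, adult-only and shared sets keyed (cell_type, direction)."""

    infant_specific: dict
    adult_only: dict
    shared: dict


def age_specific_sets(infant_sets: dict, adult_sets: dict) -> AgeSplitSets:
    """Subtract adult DE from infant DE, same cell type and direction.

    Inputs map ``(cell_type, direction)`` to `DESet`. A gene DE in
    infants and adults in opposite directions stays infant-specific.
    """
    foci = {s.species_focus for s in infant_sets.values()} | {
        s.species_focus for s in adult_sets.values()
    }
    if len(foci) > 1:
        raise ValueError(f"mixed focal species: {sorted(foci)}")
    infant_specific, adult_only, shared = {}, {}, {}
    keys = set(infant_sets) | set(adult_sets)
    for key in sorted(keys):
        ct, direction = key
        inf = infant_sets.get(key)
        adu = adult_sets.get(key)
        inf_genes = inf.genes if inf else frozenset()
        adu_genes = adu.genes if adu else frozenset()
        focus = (inf or adu).species_focus
        infant_specific[key] = DESet(focus, "infant", ct, direction,
                                     inf_genes - adu_genes)
        adult_only[key] = DESet(focus, "adult", ct, direction,
                                adu_genes - inf_genes)
        shared[key] = DESet(focus, "infant+adult", ct, direction,
                            inf_genes & adu_genes)
    return AgeSplitSets(infant_specific, adult_only, shared)


def upset_counts(sets_by_label: dict) -> pd.DataFrame:
    """Exclusive intersection sizes over membership patterns.

    ``sets_by_label`` maps a label (e.g. cell type) to a gene set; the
    returned frame has one row per non-empty exclusive pattern, and the
    pattern counts partition the union.
    """
    labels = sorted(sets_by_label)
    sets = {k: set(v.genes if isinstance(v, DESet) else v) for k, v in sets_by_label.items()}
    union = set().union(*sets.values()) if sets else set()
    patterns: dict = {}
    for g in union:
        pat = tuple(lab for lab in labels if g in sets[lab])
        patterns[pat] = patterns.get(pat, 0) + 1
    rows = [
        {"pattern": pat, "degree": len(pat), "count": n}
        for pat, n in sorted(patterns.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["pattern", "degree", "count"])


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; two empty sets give 1.0 with a warning."""
    a = set(set_a.genes if isinstance(set_a, DESet) else set_a)
    b = set(set_b.genes if isinstance(set_b, DESet) else set_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 1.0", stacklevel=2)
        return 1.0
    return len(a & b) / len(union)


def consistency_fraction(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> float:
    """Fraction of run-A DE calls re-called with the same sign in run B."""
    gain_a, loss_a = call_de(calls_a, lfc_threshold, fdr_threshold)
    gain_b, loss_b = call_de(calls_b, lfc_threshold, fdr_threshold)
    n_de = len(gain_a) + len(loss_a)
    if n_de == 0:
        warnings.warn("run A called no DE genes; consistency undefined, returning 1.0",
                      stacklevel=2)
        return 1.0
    kept = len(gain_a.genes & gain_b.genes) + len(loss_a.genes & loss_b.genes)
    return kept / n_de


def flag_confounders(deset: DESet, flag_lists: dict, universe) -> pd.DataFrame:
    """Hypergeometric enrichment of confounder flag lists in a DE set.

    ``flag_lists`` maps names (highly-variable, PMI-associated,
    sex-associated, ...) to gene sets; the universe defaults to the genes
    tested in the cell type's DE run and must contain the DE set.
    """
    universe = set(universe)
    if not set(deset.genes) <= universe:
        raise ValueError("DE set contains genes outside the stated universe")
    rows = []
    for name in sorted(flag_lists):
        res = enrich(deset.genes, flag_lists[name], universe, name=name)
        rows.append(
            {"flag_list": name, "overlap": res.k, "list_size": res.K,
             "deset_size": res.n, "universe": res.N,
             "odds_ratio": res.odds_ratio, "p": res.p}
        )
    return pd.DataFrame(rows)
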