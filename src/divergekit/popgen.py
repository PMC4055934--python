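"""Allele frequencies, gene diversity, and Jost's D pairwise differentiation.

Jost's D measures allelic differentiation between demes:

    D = ((H_T - H_S) / (1 - H_S)) * n/(n - 1),  n = number of demes (2 here)

with H_S the mean within-population gene diversity and H_T the diversity of
the pooled (unweighted mean) allele-frequency vector.  The bias-corrected
estimator uses Nei & Chesser-style corrections with the harmonic-mean sample
size of the pair:

    H_S_hat = (2*nh / (2*nh - 1)) * (1 - mean_k sum_i p_ki^2)
    H_T_hat = (1 - sum_i pbar_i^2) + H_S_hat / (2 * nh * n)

The corrected estimator can be slightly negative in near-panmictic data;
that is the price of unbiasedness, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .records import MISSING, GenotypeTable

__all__ = [
    "DestMatrix",
    "allele_frequencies",
    "gene_diversity",
    "dest_locus",
    "dest_pairwise",
    "gst_locus",
    "typed_counts_report",
]


@dataclass
class DestMatrix:
    """Pairwise multi-locus Jost's D with per-locus detail."""

    populations: List[str]
    values: np.ndarray
    per_locus: Dict[str, np.ndarray]

    def pair(self, pop_a: str, pop_b: str) -> float:
        i = self.populations.index(pop_a)
        j = self.populations.index(pop_b)
        return float(self.values[i, j])

    def to_frame(self):
        """Upper-triangular DataFrame (zero diagonal, blanks below)."""
        import pandas as pd

        k = len(self.populations)
        data = []
        for i in range(k):
            row = {"population": self.populations[i]}
            for j, name in enumerate(self.populations):
                if j < i:
                    row[name] = np.nan
                elif j == i:
                    row[name] = 0.0
                else:
                    row[name] = self.values[i, j]
            data.append(row)
        return pd.DataFrame(data)


def _pop_locus_calls(table: GenotypeTable, population: str, locus: str):
    if locus not in table.loci:
        raise KeyError(f"unknown locus {locus!r}")
    j = table.loci.index(locus)
    return [
        table.calls[i][j]
        for i in table.population_indices(population)
        if table.calls[i][j] is not MISSING
    ]


def allele_frequencies(table: GenotypeTable, population: str, locus: str
                       ) -> Tuple[Dict[int, float], int]:
    """Observed allele frequencies and the count of typed diploids."""
    calls = _pop_locus_calls(table, population, locus)
    if not calls:
        raise ValueError(
            f"no typed individuals for population {population!r} at locus "
            f"{locus!r}")
    counts: Dict[int, int] = {}
    for a, b in calls:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(calls)
    freqs = {allele: c / total for allele, c in sorted(counts.items())}
    return freqs, len(calls)


def gene_diversity(freqs, n_typed: Optional[int] = None,
                   correction: bool = False) -> float:
    """Expected heterozygosity H = 1 - sum p_i^2.

    With ``correction`` the small-sample unbiased version
    (2n/(2n-1)) * (1 - sum p_i^2) is returned; it needs n_typed >= 2.
    """
    if isinstance(freqs, dict):
        p = np.array(list(freqs.values()), dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    h = 1.0 - float(np.sum(p * p))
    if correction:
        if n_typed is None or n_typed < 2:
            raise ValueError("correction requires n_typed >= 2")
        h *= 2.0 * n_typed / (2.0 * n_typed - 1.0)
    return h


def _freq_vectors(table, pop_a, pop_b, locus):
    fa, na = allele_frequencies(table, pop_a, locus)
    fb, nb = allele_frequencies(table, pop_b, locus)
    alleles = sorted(set(fa) | set(fb))
    pa = np.array([fa.get(al, 0.0) for al in alleles])
    pb = np.array([fb.get(al, 0.0) for al in alleles])
    return pa, pb, na, nb


def dest_locus(table: GenotypeTable, pop_a: str, pop_b: str, locus: str,
               correction: bool = True) -> float:
    """Jost's D between two populations at one locus."""
    pa, pb, na, nb = _freq_vectors(table, pop_a, pop_b, locus)
    return dest_from_frequencies(pa, pb, na, nb, correction=correction)


def dest_from_frequencies(pa, pb, na: int, nb: int,
                          correction: bool = True) -> float:
    """Jost's D for two demes from allele-frequency vectors.

    ``na``/``nb`` are typed-diploid counts, used only by the bias
    correction (harmonic-mean sample size nh).
    """
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    pbar = (pa + pb) / 2.0
    hs_plug = 1.0 - 0.5 * (float(np.sum(pa ** 2)) + float(np.sum(pb ** 2)))
    ht_plug = 1.0 - float(np.sum(pbar ** 2))
    if correction:
        if min(na, nb) < 2:
            raise ValueError("bias correction requires >= 2 typed diploids")
        nh = 2.0 / (1.0 / na + 1.0 / nb)
        hs = (2.0 * nh / (2.0 * nh - 1.0)) * hs_plug
        ht = ht_plug + hs / (2.0 * nh * 2.0)
    else:
        hs, ht = hs_plug, ht_plug
    if hs >= 1.0:
        raise ValueError("H_S = 1: Jost's D undefined (division by zero)")
    return ((ht - hs) / (1.0 - hs)) * 2.0


def gst_locus(table: GenotypeTable, pop_a: str, pop_b: str, locus: str,
              correction: bool = False) -> float:
    """G_ST = (H_T - H_S)/H_T, offered for contrast with Jost's D."""
    pa, pb, na, nb = _freq_vectors(table, pop_a, pop_b, locus)
    pbar = (pa + pb) / 2.0
    hs = 1.0 - 0.5 * (float(np.sum(pa ** 2)) + float(np.sum(pb ** 2)))
    ht = 1.0 - float(np.sum(pbar ** 2))
    if correction:
        nh = 2.0 / (1.0 / na + 1.0 / nb)
        hs = (2.0 * nh / (2.0 * nh - 1.0)) * hs
        ht = ht + hs / (2.0 * nh * 2.0)
    if ht == 0:
        raise ValueError("H_T = 0: G_ST undefined")
    return (ht - hs) / ht


def dest_pairwise(table: GenotypeTable, correction: bool = True,
                  aggregation: str = "arithmetic") -> DestMatrix:
    """Multi-locus pairwise Jost's D for every population pair.

    Per-locus values are combined by the arithmetic mean (default) or the
    harmonic mean.  The harmonic mean is undefined at non-positive values,
    which near-panmictic data produce routinely; such values are floored at
    zero, and a locus at exactly zero forces the harmonic mean to zero.
    """
    if len(table.populations) < 2:
        raise ValueError("need >= 2 populations for pairwise D")
    if table.n_loci < 1:
        raise ValueError("need >= 1 locus")
    if aggregation not in ("arithmetic", "harmonic"):
        raise ValueError("aggregation must be 'arithmetic' or 'harmonic'")
    k = len(table.populations)
    per_locus = {
        locus: np.zeros((k, k)) for locus in table.loci
    }
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pop_a, pop_b = table.populations[i], table.populations[j]
            locus_values = []
            for locus in table.loci:
                d = dest_locus(table, pop_a, pop_b, locus,
                               correction=correction)
                per_locus[locus][i, j] = per_locus[locus][j, i] = d
                locus_values.append(d)
            arr = np.array(locus_values)
            if aggregation == "arithmetic":
                agg = float(arr.mean())
            else:
                floored = np.clip(arr, 0.0, None)
                if np.any(floored == 0.0):
                    agg = 0.0
                else:
                    agg = float(len(floored) / np.sum(1.0 / floored))
            values[i, j] = values[j, i] = agg
    return DestMatrix(populations=list(table.populations), values=values,
                      per_locus=per_locus)


def typed_counts_report(table: GenotypeTable):
    """Per-population x locus typed-diploid counts (HWE screening is out of
    scope; this report supports manual locus vetting)."""
    import pandas as pd

    rows = []
    for pop in table.populations:
        row = {"population": pop}
        for locus in table.loci:
            row[locus] = len(_pop_locus_calls(table, pop, locus))
        rows.append(row)
    return pd.DataFrame(rows)
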