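"""Species and strain effects on monoculture growth parameters.

Species and strain-within-species form a hierarchy: strains are nested in
species and treated as a random modulation of the species mean.  For the
(near-)balanced designs produced by microplate layouts this mixed model is
testable exactly through the expected-mean-square ANOVA decomposition:

* species (fixed) is tested against the strain-within-species mean square,
* strain-within-species (random) is tested against the residual.

This coincides with the REML mixed-model F-tests for balanced data while
remaining free of any optimizer.  Per-species compact letter displays use
Tukey-Kramer comparisons of species means with the strain mean square as
the error term (the correct yardstick when strains are random draws).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

log = logging.getLogger(__name__)

__all__ = [
    "NestedGrowthAnova",
    "NestedAnovaResults",
    "nested_anova",
    "species_letter_groups",
    "compact_letter_display",
]


class NestedGrowthAnova:
    """Hierarchical (species / strain-within-species) ANOVA model.

    Parameters
    ----------
    values : 1-D array of replicate parameter values
    species, strain : label sequences aligned with ``values``
    """

    def __init__(self, values, species, strain, parameter: str = "value"):
        self.values = np.asarray(values, dtype=float)
        self.species = np.asarray(species, dtype=object)
        self.strain = np.asarray(strain, dtype=object)
        self.parameter = parameter
        if not (len(self.values) == len(self.species) == len(self.strain)):
            raise AnalysisError("values, species and strain must have equal length")
        if np.isnan(self.values).any():
            keep = ~np.isnan(self.values)
            self.values, self.species, self.strain = self.values[keep], self.species[keep], self.strain[keep]
        if len(self.values) < 4:
            raise AnalysisError("too few observations for a nested ANOVA")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str,
                       species_col: str = "species", strain_col: str = "strain") -> "NestedGrowthAnova":
        return cls(df[value_col].to_numpy(), df[species_col].to_numpy(),
                   df[strain_col].to_numpy(), parameter=value_col)

    def fit(self) -> "NestedAnovaResults":
        y, sp, st = self.values, self.species, self.strain
        grand = y.mean()
        species_levels = sorted(set(sp))
        # strains are nested: identify them by (species, strain)
        strain_keys = [(a, b) for a, b in zip(sp, st)]
        strain_levels = sorted(set(strain_keys))

        ss_species = 0.0
        species_stats = {}
        for s in species_levels:
            ys = y[sp == s]
            ss_species += len(ys) * (ys.mean() - grand) ** 2
            species_stats[s] = (float(ys.mean()), float(ys.std(ddof=1)) if len(ys) > 1 else float("nan"), len(ys))
        df_species = len(species_levels) - 1

        ss_strain = 0.0
        ss_res = 0.0
        strains_per_species = {s: 0 for s in species_levels}
        for key in strain_levels:
            s, _ = key
            mask = np.array([k == key for k in strain_keys])
            yk = y[mask]
            ys_mean = y[sp == s].mean()
            ss_strain += len(yk) * (yk.mean() - ys_mean) ** 2
            ss_res += float(np.sum((yk - yk.mean()) ** 2))
            strains_per_species[s] += 1
        df_strain = len(strain_levels) - len(species_levels)
        df_res = len(y) - len(strain_levels)
        if df_species < 1 or df_res < 1:
            raise AnalysisError("need at least 2 species and replicated strains")

        single = [s for s, m in strains_per_species.items() if m < 2]
        ms_species = ss_species / df_species
        ms_res = ss_res / df_res
        if df_strain >= 1:
            ms_strain = ss_strain / df_strain
            strain_F = ms_strain / ms_res
            strain_p = float(stats.f.sf(strain_F, df_strain, df_res))
        else:
            ms_strain = float("nan")
            strain_F = float("nan")
            strain_p = float("nan")
        if df_strain >= 1 and not single:
            species_F = ms_species / ms_strain
            species_den_df = df_strain
        else:
            # no replicated strains to estimate the strain stratum: fall
            # back to the residual denominator (classical one-way ANOVA)
            if single:
                log.warning("species with a single strain (%s): species test uses the residual denominator", single)
            species_F = ms_species / ms_res
            species_den_df = df_res
        species_p = float(stats.f.sf(species_F, df_species, species_den_df))

        n_per_species = {s: species_stats[s][2] for s in species_levels}
        balanced = len(set(n_per_species.values())) == 1
        if not balanced:
            log.warning("unbalanced species group sizes %s: EMS decomposition is approximate", n_per_species)

        return NestedAnovaResults(
            parameter=self.parameter,
            species_F=float(species_F), species_p=species_p,
            species_df=(df_species, species_den_df),
            strain_F=float(strain_F), strain_p=strain_p,
            strain_df=(df_strain, df_res),
            ms_species=float(ms_species), ms_strain=float(ms_strain), ms_residual=float(ms_res),
            species_means={s: v[0] for s, v in species_stats.items()},
            species_sds={s: v[1] for s, v in species_stats.items()},
            species_n=n_per_species,
            error_df=species_den_df,
            error_ms=float(ms_strain) if (df_strain >= 1 and not single) else float(ms_res),
        )


@dataclass(frozen=True)
class NestedAnovaResults:
    """F-tests and per-species summaries of the hierarchical ANOVA."""

    parameter: str
    species_F: float
    species_p: float
    species_df: tuple[int, int]
    strain_F: float
    strain_p: float
    strain_df: tuple[int, int]
    ms_species: float
    ms_strain: float
    ms_residual: float
    species_means: dict
    species_sds: dict
    species_n: dict
    error_df: int
    error_ms: float

    def tukey_pvalues(self) -> dict[tuple[str, str], float]:
        """Tukey-Kramer p-values for all species pairs (strain-MS error)."""
        levels = sorted(self.species_means)
        out = {}
        k = len(levels)
        for i in range(k):
            for j in range(i + 1, k):
                a, b = levels[i], levels[j]
                se = np.sqrt(self.error_ms * 0.5 * (1.0 / self.species_n[a] + 1.0 / self.species_n[b]))
                q = abs(self.species_means[a] - self.species_means[b]) / se
                out[(a, b)] = float(stats.studentized_range.sf(q, k, self.error_df))
        return out

    def letter_groups(self, alpha: float = 0.05) -> dict[str, str]:
        """Compact letter display: species sharing a letter do not differ."""
        pvals = self.tukey_pvalues()
        significant = [pair for pair, p in pvals.items() if p < alpha]
        return compact_letter_display(sorted(self.species_means), significant, self.species_means)

    def summary(self) -> str:
        lines = [
            f"Nested ANOVA — {self.parameter}",
            "=" * 58,
            f"{'effect':<22}{'F':>10}{'df':>10}{'p':>14}",
            f"{'species (vs strain MS)':<22}{self.species_F:>10.4g}"
            f"{str(self.species_df):>10}{self.species_p:>14.4g}",
            f"{'strain (vs residual)':<22}{self.strain_F:>10.4g}"
            f"{str(self.strain_df):>10}{self.strain_p:>14.4g}",
            "-" * 58,
            f"{'species':<10}{'mean':>12}{'sd':>12}{'n':>6}{'group':>8}",
        ]
        letters = self.letter_groups()
        for s in sorted(self.species_means):
            lines.append(
                f"{s:<10}{self.species_means[s]:>12.4g}{self.species_sds[s]:>12.4g}"
                f"{self.species_n[s]:>6d}{letters[s]:>8}"
            )
        return "\n".join(lines)


def compact_letter_display(levels, significant_pairs, means=None) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant_pairs`` are unordered level pairs that must not share a
    letter.  Letters are ordered by descending group mean when ``means`` is
    given, else by level order.
    """
    groups = [set(levels)]
    for a, b in significant_pairs:
        nxt = []
        for g in groups:
            if a in g and b in g:
                nxt.append(g - {a})
                nxt.append(g - {b})
            else:
                nxt.append(g)
        # absorb groups contained in another
        groups = []
        for g in sorted(nxt, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    if means is not None:
        groups.sort(key=lambda g: -max(means[l] for l in g))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {l: "" for l in levels}
    for letter, g in zip(letters, groups):
        for l in sorted(g):
            out[l] += letter
    return {l: "".join(sorted(v)) for l, v in out.items()}


def nested_anova(values, species, strain, parameter: str = "value") -> NestedAnovaResults:
    """Functional wrapper over :class:`NestedGrowthAnova`."""
    return NestedGrowthAnova(values, species, strain, parameter).fit()


def species_letter_groups(result: NestedAnovaResults, alpha: float = 0.05) -> dict[str, str]:
    """Letter assignment for a fitted nested ANOVA (see Results method)."""
    return result.letter_groups(alpha)
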