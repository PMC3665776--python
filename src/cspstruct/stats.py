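"""Variation tables and contingency statistics for family comparisons.

The central quantity is per-ortholog-group charge variation: for each
analyzed surface column of the alignment, whether the charge class of the
residue differs in at least one species. Group-level counts feed a Pearson
chi-square for heterogeneity across groups, and the overlap between
positively selected sites and charge-variable sites is tested with Fisher's
exact test.

Chi-square p-values come from the chi-square upper tail without continuity
correction; Fisher's two-sided p uses the minimum-likelihood convention
(the sum of point probabilities no larger than the observed table's).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .family_map import AlignedFamily, charge_class

logger = logging.getLogger(__name__)

__all__ = [
    "VariationRow",
    "VariationTable",
    "ContingencyResult",
    "SelectedSiteRow",
    "charge_variation_table",
    "variation_table_from_counts",
    "chisq_independence",
    "fisher_exact_2x2",
    "selected_sites_summary",
    "enrichment_test",
    "format_percent",
]


def format_percent(numerator: int, denominator: int) -> str:
    """Percentage at 2 decimals with half-up rounding, e.g. ``'42.03'``."""
    if denominator == 0:
        raise ZeroDivisionError("cannot format a percentage with zero denominator")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return str(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class VariationRow:
    group: str
    n_surface: int
    n_variable: int

    @property
    def fraction(self) -> float:
        return self.n_variable / self.n_surface if self.n_surface else 0.0

    @property
    def percent(self) -> str:
        return format_percent(self.n_variable, self.n_surface)


@dataclass
class VariationTable:
    rows: dict[str, VariationRow] = field(default_factory=dict)

    def contingency(self) -> list[list[int]]:
        """2 x G variable / non-variable table over the groups, in row order."""
        groups = list(self.rows)
        return [[self.rows[g].n_variable for g in groups],
                [self.rows[g].n_surface - self.rows[g].n_variable for g in groups]]


def variation_table_from_counts(counts: dict[str, tuple[int, int]]) -> VariationTable:
    """Build a :class:`VariationTable` from (n_variable, n_surface) count pairs."""
    rows = {}
    for group, (n_var, n_surf) in counts.items():
        if not 0 <= n_var <= n_surf:
            raise ValueError(f"group {group}: {n_var} variable of {n_surf} surface is inconsistent")
        rows[group] = VariationRow(group=group, n_surface=n_surf, n_variable=n_var)
    return VariationTable(rows=rows)


def charge_variation_table(family: AlignedFamily, surface_columns: dict[str, list[int]],
                           species: set[str] | None = None,
                           gap_is_change: bool = False) -> VariationTable:
    """Per-group counts of surface columns whose charge class varies across species.

    ``surface_columns`` maps group label to analyzed alignment columns
    (1-based). A column is variable when the charge classes of the species'
    letters there are not all equal. Gaps do not constitute a charge state
    unless ``gap_is_change``; a column with fewer than 2 non-gap species is
    dropped from the analyzed count.
    """
    by_group = family.by_group()
    table = VariationTable()
    for group, columns in surface_columns.items():
        recs = by_group.get(group, [])
        if species is not None:
            missing = species - {r.species for r in recs}
            if missing:
                logger.warning("group %s: species %s missing, skipped", group, sorted(missing))
            recs = [r for r in recs if r.species in species]
        if len(recs) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 species; cannot assess variation")
        n_analyzed = 0
        n_variable = 0
        for col in columns:
            letters = [r.sequence[col - 1] for r in recs]
            if gap_is_change:
                classes = {("gap" if l == "-" else charge_class(l)) for l in letters}
            else:
                nongap = [l for l in letters if l != "-"]
                if len(nongap) < 2:
                    logger.debug("group %s column %d: <2 non-gap species, dropped", group, col)
                    continue
                classes = {charge_class(l) for l in nongap}
            n_analyzed += 1
            if len(classes) > 1:
                n_variable += 1
        table.rows[group] = VariationRow(group=group, n_surface=n_analyzed, n_variable=n_variable)
    return table


@dataclass
class ContingencyResult:
    observed: list[list[int]]
    statistic: float
    df: int
    p_value: float
    method: str


def chisq_independence(observed) -> ContingencyResult:
    """Pearson chi-square test of independence on an R x C count table.

    No continuity correction; expected counts from the margins; p-value from
    the chi-square upper tail with df = (R-1)(C-1).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("observed table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a row or column margin is zero")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return ContingencyResult(observed=np.asarray(observed).astype(int).tolist(),
                             statistic=float(stat), df=int(df), p_value=float(p),
                             method="pearson-chi2")


def fisher_exact_2x2(observed, sided: str = "two") -> ContingencyResult:
    """Fisher's exact test on a 2x2 table.

    One-sided is the upper (enrichment) tail; two-sided sums the
    hypergeometric point probabilities at most as large as the observed
    table's (minimum-likelihood convention).
    """
    obs = np.asarray(observed)
    if obs.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(obs.dtype, np.integer):
        if not np.allclose(obs, np.round(obs)):
            raise ValueError("counts must be integers")
        obs = np.round(obs).astype(int)
    if obs.sum() == 0:
        raise ValueError("table total must be positive")
    alternative = {"one": "greater", "two": "two-sided"}.get(sided)
    if alternative is None:
        raise ValueError("sided must be 'one' or 'two'")
    _, p = sps.fisher_exact(obs, alternative=alternative)
    return ContingencyResult(observed=obs.tolist(), statistic=float(p), df=1,
                             p_value=float(p), method=f"fisher-exact-{sided}-sided")


@dataclass
class SelectedSiteRow:
    site_label: str
    reference_number: int
    mean_rel_acc: float
    stdev_rel_acc: float
    single_model: bool
    is_binding: bool
    variants: frozenset[str]
    has_charge_variation: bool


def selected_sites_summary(sites, family: AlignedFamily, cmap,
                           rel_acc_by_model: list[dict[int, float]],
                           binding_numbers) -> list[SelectedSiteRow]:
    """Summarize positively selected sites: accessibility, binding, variants.

    ``sites`` are (label, reference residue number) pairs; ``rel_acc_by_model``
    gives one reference-numbered accessibility map per structural model. The
    variant set pools the letters of every family member at the site's
    alignment column; charge variation means the variants span at least two
    charge classes.
    """
    binding_numbers = set(binding_numbers)
    rows: list[SelectedSiteRow] = []
    for label, num in sites:
        col = cmap.column(num)  # raises if the site is outside the alignment map
        values = [m[num] for m in rel_acc_by_model if num in m]
        if not values:
            raise ValueError(f"site {label}: no model provides accessibility for residue {num}")
        mean = float(np.mean(values))
        single = len(values) == 1
        stdev = 0.0 if single else float(np.std(values, ddof=1))
        if single:
            logger.info("site %s: single model, stdev reported as 0 by convention", label)
        variants = frozenset(r.sequence[col - 1] for r in family.records) - {"-"}
        classes = {charge_class(v) for v in variants if v != "X"}
        rows.append(SelectedSiteRow(
            site_label=label, reference_number=num, mean_rel_acc=mean,
            stdev_rel_acc=stdev, single_model=single,
            is_binding=num in binding_numbers, variants=variants,
            has_charge_variation=len(classes) > 1))
    return rows


def enrichment_test(selected_sites, other_sites, variable: dict,
                    sided: str = "two") -> ContingencyResult:
    """Fisher test for elevated charge variation among selected surface sites.

    Builds the 2x2 table [[variable, non-variable] for the selected sites;
    the same for the remaining sites] from the ``variable`` flag mapping.
    """
    sel = set(selected_sites)
    oth = set(other_sites)
    if sel & oth:
        raise ValueError(f"site sets overlap: {sorted(sel & oth)}")
    table = [[sum(variable[s] for s in sel), sum(not variable[s] for s in sel)],
             [sum(variable[s] for s in oth), sum(not variable[s] for s in oth)]]
    return fisher_exact_2x2(table, sided=sided)
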