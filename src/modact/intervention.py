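"""In-silico gene interventions: KOs, over-expressions, drugs, auto-KO search.

Two KO dialects are supported: ``ko_hard`` sets expression to 0 (manual
KO simulation) and ``ko_soft`` multiplies it by 0.01 (the auto-KO
search's perturbation).  Fold changes of module activity before/after an
intervention use a small pseudo-activity to stay finite at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ModelError
from .expression import Design, ExpressionMatrix
from .graph import ModuleSet
from .prediction import fit_classifier, _design_xy
from .propagation import ActivityMatrix, activity_matrix

__all__ = [
    "Action",
    "InterventionSpec",
    "DrugTargetMap",
    "KOEffectRow",
    "KORankingEntry",
    "apply_intervention",
    "ko_effect",
    "drug_effect",
    "auto_knockout",
    "read_intervention_spec",
    "read_drug_map",
    "PSEUDO_ACTIVITY",
    "SOFT_KO_MULTIPLIER",
]

log = logging.getLogger(__name__)

PSEUDO_ACTIVITY = 1e-6
SOFT_KO_MULTIPLIER = 0.01

_ACTIONS = ("ko_hard", "ko_soft", "overexpress", "scale", "set")


@dataclass(frozen=True)
class Action:
    kind: str
    value: float | None = None

    def __post_init__(self):
        if self.kind not in _ACTIONS:
            raise DataError(f"unknown intervention action {self.kind!r} (expected one of {_ACTIONS})")
        if self.kind in ("scale", "set") and self.value is None:
            raise DataError(f"action {self.kind!r} requires a value")
        if self.kind == "set" and not (0.0 <= float(self.value) <= 1.0):
            raise DataError(f"'set' value must be in [0,1], got {self.value}")

    def apply(self, x):
        if self.kind == "ko_hard":
            return x * 0.0
        if self.kind == "ko_soft":
            return x * SOFT_KO_MULTIPLIER
        if self.kind == "overexpress":
            return x * 0.0 + 1.0
        if self.kind == "scale":
            return x * float(self.value)
        return x * 0.0 + float(self.value)


class InterventionSpec:
    """One action per gene."""

    def __init__(self, actions: dict[str, Action] | None = None):
        self.actions: dict[str, Action] = dict(actions or {})

    def add(self, gene: str, action: Action) -> None:
        prev = self.actions.get(gene)
        if prev is not None and prev != action:
            raise DataError(f"conflicting actions for gene {gene!r}: {prev} vs {action}")
        self.actions[gene] = action

    def merged(self, other: "InterventionSpec") -> "InterventionSpec":
        out = InterventionSpec(self.actions)
        for g, a in other.actions.items():
            out.add(g, a)
        return out

    @property
    def genes(self) -> list[str]:
        return list(self.actions)

    def __len__(self) -> int:
        return len(self.actions)

    @classmethod
    def ko_hard(cls, genes) -> "InterventionSpec":
        return cls({g: Action("ko_hard") for g in genes})

    @classmethod
    def ko_soft(cls, genes) -> "InterventionSpec":
        return cls({g: Action("ko_soft") for g in genes})

    @classmethod
    def overexpress(cls, genes) -> "InterventionSpec":
        return cls({g: Action("overexpress") for g in genes})


class DrugTargetMap:
    """drug name -> [(gene, effect)] with effect in {inhibit, activate}."""

    def __init__(self, targets: dict[str, list[tuple[str, str]]]):
        for drug, genes in targets.items():
            if not genes:
                raise DataError(f"drug {drug!r} has an empty target list")
            for gene, effect in genes:
                if effect not in ("inhibit", "activate"):
                    raise DataError(f"drug {drug!r}, gene {gene!r}: unknown effect {effect!r}")
        self.targets = targets

    def spec_for(self, drugs) -> InterventionSpec:
        spec = InterventionSpec()
        for drug in drugs:
            if drug not in self.targets:
                raise DataError(f"unknown drug {drug!r}; map has {sorted(self.targets)}")
            for gene, effect in self.targets[drug]:
                spec.add(gene, Action("ko_soft" if effect == "inhibit" else "overexpress"))
        return spec


@dataclass
class KOEffectRow:
    module_id: str
    activity_before: float
    activity_after: float
    fold_change: float
    flagged: bool


@dataclass
class KORankingEntry:
    gene: str
    p_target_before: float
    p_target_after: float
    change: float


def read_intervention_spec(path) -> InterventionSpec:
    """TSV: gene<TAB>action[<TAB>value], no header."""
    spec = InterventionSpec()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise DataError(f"{path}:{lineno}: expected 2-3 fields, got {len(parts)}")
            value = float(parts[2]) if len(parts) == 3 else None
            spec.add(parts[0].strip(), Action(parts[1].strip(), value))
    return spec


def read_drug_map(path) -> DrugTargetMap:
    """TSV: drug<TAB>gene<TAB>effect, no header."""
    targets: dict[str, list[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DataError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            drug, gene, effect = (p.strip() for p in parts)
            targets.setdefault(drug, []).append((gene, effect))
    return DrugTargetMap(targets)


def apply_intervention(
    expr: ExpressionMatrix,
    spec: InterventionSpec,
    samples: list[str] | None = None,
) -> ExpressionMatrix:
    """Return a modified copy of the expression matrix.

    Only the listed samples are touched (all samples when ``samples`` is
    None).  Genes absent from the matrix are skipped with a log message.
    Resulting values are clipped to [0,1].
    """
    if samples is None:
        samples = expr.samples
    if len(samples) == 0:
        raise DataError("empty sample subset for intervention")
    unknown = [s for s in samples if s not in expr.data.columns]
    if unknown:
        raise DataError(f"unknown sample(s) in intervention subset: {unknown}")
    df = expr.data.copy()
    for gene, action in spec.actions.items():
        if gene not in df.index:
            log.info("intervention gene %s not in expression matrix; skipped", gene)
            continue
        df.loc[gene, samples] = np.clip(action.apply(df.loc[gene, samples].to_numpy()), 0.0, 1.0)
    return ExpressionMatrix(df)


def _column_activities(modules: ModuleSet, column: pd.Series, terminal_rule: str) -> pd.Series:
    expr = ExpressionMatrix(column.to_frame())
    act = activity_matrix(modules, expr, terminal_rule=terminal_rule)
    return act.data.iloc[:, 0]


def ko_effect(
    modules: ModuleSet,
    expr_column: pd.Series,
    spec: InterventionSpec,
    threshold: float = 2.0,
    terminal_rule: str = "mean",
) -> list[KOEffectRow]:
    """Module-activity fold changes of one sample under an intervention.

    Only two single conditions are compared, so no statistical test is
    run; modules whose fold change crosses the threshold (default 2) are
    flagged.  Rows are sorted by |log2 fold change| descending.
    """
    if threshold <= 1:
        raise DataError(f"fold-change threshold must be > 1, got {threshold}")
    before = _column_activities(modules, expr_column, terminal_rule)
    modified = pd.Series(expr_column, copy=True)
    for gene, action in spec.actions.items():
        if gene in modified.index:
            modified.loc[gene] = float(np.clip(action.apply(modified.loc[gene]), 0.0, 1.0))
        else:
            log.info("intervention gene %s not in expression column; skipped", gene)
    after = _column_activities(modules, modified, terminal_rule)
    rows = []
    for module_id in modules.module_ids:
        b, a = float(before[module_id]), float(after[module_id])
        fc = (a + PSEUDO_ACTIVITY) / (b + PSEUDO_ACTIVITY)
        rows.append(
            KOEffectRow(
                module_id=module_id,
                activity_before=b,
                activity_after=a,
                fold_change=fc,
                flagged=bool(fc >= threshold or fc <= 1.0 / threshold),
            )
        )
    rows.sort(key=lambda r: (-abs(math.log2(r.fold_change)), r.module_id))
    return rows


def drug_effect(
    modules: ModuleSet,
    expr_column: pd.Series,
    drugs: list[str],
    drug_map: DrugTargetMap,
    threshold: float = 2.0,
    extra_spec: InterventionSpec | None = None,
    terminal_rule: str = "mean",
) -> list[KOEffectRow]:
    """Effect of one or more drugs (optionally combined with extra gene
    actions): inhibit -> soft KO, activate -> over-expression, then
    delegates to :func:`ko_effect`."""
    spec = drug_map.spec_for(drugs)
    if extra_spec is not None:
        spec = spec.merged(extra_spec)
    in_modules = set(modules.gene_universe)
    if not any(g in in_modules for g in spec.genes):
        log.warning("no drug target is present in any module; all fold changes will be 1")
    return ko_effect(modules, expr_column, spec, threshold=threshold, terminal_rule=terminal_rule)


def auto_knockout(
    modules: ModuleSet,
    expr: ExpressionMatrix,
    design: Design,
    source_class: str,
    target_class: str,
    seed: int = 0,
    multiplier: float = SOFT_KO_MULTIPLIER,
    terminal_rule: str = "mean",
    balance: bool = True,
    genes: list[str] | None = None,
) -> list[KORankingEntry]:
    """Rank single-gene KOs by how much they shift source-class samples
    toward the target class.

    An RF classifier is trained on the module activities of both classes.
    For each gene of the module gene universe, that gene's expression is
    scaled by ``multiplier`` in every source-class sample, the affected
    modules are recomputed, and the mean predicted probability of the
    target class over source samples is recorded.  Entries are sorted by
    probability change (after - before) descending, ties broken by gene id.

    ``genes`` restricts or extends the candidate list (default: the
    module gene universe); a candidate in no module has change exactly 0.
    """
    for label in (source_class, target_class):
        if label not in design.classes:
            raise DataError(f"unknown class label {label!r}; design has {design.classes}")
    act = activity_matrix(modules, expr, terminal_rule=terminal_rule)
    X, y, _ = _design_xy(act, design)
    keep = np.isin(y, [source_class, target_class])
    if len(np.unique(y[keep])) < 2:
        raise ModelError("both classes must be present in the activity matrix")
    clf = fit_classifier(X[keep], y[keep], algorithm="rf", seed=seed, balance=balance)
    target_col = list(clf.classes_).index(target_class)

    source_samples = [s for s in act.samples if s in design and design[s] == source_class]
    if len(source_samples) < 2 or len(design.samples_of(target_class)) < 2:
        raise DataError("need >= 2 samples per class for the auto-KO search")
    src_act = act.data.loc[:, source_samples]  # modules x source samples

    def _mean_target_prob(frame: pd.DataFrame) -> float:
        proba = clf.predict_proba(frame.to_numpy().T)
        return float(np.mean(proba[:, target_col]))

    p_before = _mean_target_prob(src_act)
    src_expr = expr.subset_samples(source_samples)

    candidates = sorted(modules.gene_universe) if genes is None else sorted(genes)
    entries = []
    for gene in candidates:
        affected = modules.modules_with_gene(gene)
        if multiplier == 1.0 or gene not in expr.data.index or not affected:
            entries.append(KORankingEntry(gene, p_before, p_before, 0.0))
            continue
        ko_expr = src_expr.data.copy()
        ko_expr.loc[gene] = np.clip(ko_expr.loc[gene].to_numpy() * multiplier, 0.0, 1.0)
        sub = ModuleSet(graphs=tuple(modules.get(m) for m in affected))
        new_rows = activity_matrix(sub, ExpressionMatrix(ko_expr), terminal_rule=terminal_rule)
        frame = src_act.copy()
        frame.loc[list(affected)] = new_rows.data.to_numpy()
        p_after = _mean_target_prob(frame)
        entries.append(KORankingEntry(gene, p_before, p_after, p_after - p_before))
    entries.sort(key=lambda e: (-e.change, e.gene))
    return entries
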