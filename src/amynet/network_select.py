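"""Automated selection of networks of interest by spatial template matching.

Candidate component maps (e.g. the 35 group-ICA components of a typical
resting-state decomposition) are matched to named binary template masks by
multiple spatial regression: each mask, flattened over brain voxels, is
regressed on *all* component maps jointly, and the component with the
largest positive coefficient wins the template.  By default assignment is
greedy one-to-one (a component cannot win two templates), matching the
convention of selecting distinct components for distinct canonical networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import VolumeMap


class DegeneracyError(ValueError):
    """Rank-deficient component set (duplicate or collinear components)."""


@dataclass
class TemplateMatch:
    component_index: int
    template_name: str
    beta: float   # multiple-regression coefficient of the winning component
    rank: int     # 1 = the template's top-coefficient component won it


def _stack(components: list[VolumeMap]) -> np.ndarray:
    shapes = {c.shape for c in components}
    if len(shapes) != 1:
        raise ValueError("all component maps must share one grid")
    X = np.column_stack([np.nan_to_num(c.values, nan=0.0).ravel() for c in components])
    return X


def match_components(components: list[VolumeMap],
                     templates: dict[str, VolumeMap],
                     allow_reuse: bool = False) -> list[TemplateMatch]:
    """Match each template mask to one component by multiple regression.

    For every template the binary mask is the regression response and the
    component maps (plus an intercept) are the joint predictors.  Duplicate
    components make the design rank-deficient and raise
    :class:`DegeneracyError` naming the offending pair.
    """
    if not components or not templates:
        raise ValueError("need at least one component and one template")
    X = _stack(components)
    Xc = X - X.mean(axis=0)
    # detect duplicates explicitly so the error can name them
    norms = np.linalg.norm(Xc, axis=0)
    if np.any(norms == 0):
        flat = [i for i in range(X.shape[1]) if norms[i] == 0]
        raise DegeneracyError(f"constant (information-free) components: {flat}")
    corr = (Xc / norms).T @ (Xc / norms)
    dup = [(i, j) for i in range(len(components)) for j in range(i + 1, len(components))
           if abs(corr[i, j]) > 1.0 - 1e-10]
    if dup:
        raise DegeneracyError(f"duplicate/collinear component pairs: {dup}")
    design = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegeneracyError("component design matrix is rank-deficient")

    betas: dict[str, np.ndarray] = {}
    for name, tmpl in templates.items():
        if tmpl.shape != components[0].shape:
            raise ValueError(f"template {name!r} not on the component grid")
        y = np.nan_to_num(tmpl.values, nan=0.0).ravel()
        b, *_ = np.linalg.lstsq(design, y, rcond=None)
        betas[name] = b[1:]  # drop intercept

    # numerically equal coefficients (duplicate overlap) must tie-break
    # toward the lower component index, so comparisons use a rounded key
    def _key(b):
        return round(float(b), 9)

    def _rank(b_all, comp):
        order = sorted(range(len(b_all)), key=lambda i: (-_key(b_all[i]), i))
        return order.index(comp) + 1

    matches: list[TemplateMatch] = []
    if allow_reuse:
        for name, b in betas.items():
            comp = min(range(len(b)), key=lambda i: (-_key(b[i]), i))
            matches.append(TemplateMatch(comp, name, float(b[comp]), _rank(b, comp)))
        return matches

    # greedy one-to-one: repeatedly take the largest remaining coefficient,
    # ties broken toward the lower component index (then template order)
    taken: set[int] = set()
    names = list(betas)
    assigned: dict[str, TemplateMatch] = {}
    while len(assigned) < len(names):
        best = None
        for pos, name in enumerate(names):
            if name in assigned:
                continue
            for comp in range(len(components)):
                if comp in taken:
                    continue
                key = (_key(betas[name][comp]), -comp, -pos)
                if best is None or key > best[0]:
                    best = (key, name, comp)
        _, name, comp = best
        b_all = betas[name]
        assigned[name] = TemplateMatch(comp, name, float(b_all[comp]), _rank(b_all, comp))
        taken.add(comp)
    return [assigned[n] for n in names]
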