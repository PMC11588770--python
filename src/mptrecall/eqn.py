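"""Reading and writing MPT models in the EQN text format.

EQN is the line-oriented community format for MPT models: one line per
branch with three whitespace-separated fields — tree label, category
label, and the branch term as a ``*``-separated product of ``param`` and
``(1-param)`` factors, optionally prefixed by an integer coefficient
(``2*u*(1-u)``) for branches that collapse interchangeable paths.
``#`` starts a comment; a leading line that is a single integer (the
branch count emitted by some legacy tools) is accepted and ignored.
"""

from __future__ import annotations

import re

from .models import Branch, MPTModel, MPTValidationError, Tree

__all__ = ["parse_eqn", "render_eqn", "EQNParseError"]

_FACTOR_RE = re.compile(r"^(?:\(1-([A-Za-z_][\w.]*)\)|([A-Za-z_][\w.]*))$")


class EQNParseError(MPTValidationError):
    """Malformed EQN input; the message names the offending line."""


def parse_eqn(text: str) -> MPTModel:
    """Parse EQN text into a validated :class:`MPTModel`.

    Tree and category order follow first appearance.  Raises
    :class:`EQNParseError` on malformed terms and
    :class:`~mptrecall.models.MPTValidationError` (from model validation)
    when a tree's branches do not sum to one, e.g. a missing branch.
    """
    trees: dict[str, dict] = {}
    params: list[str] = []
    lines = text.splitlines()
    body: list[tuple[int, str]] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            body.append((i, line))
    if body and re.fullmatch(r"\d+", body[0][1]):
        body = body[1:]  # legacy header: number of lines
    if not body:
        raise EQNParseError("empty EQN input")

    for lineno, line in enumerate_branches(body):
        fields = line.split(None, 2)
        if len(fields) != 3:
            raise EQNParseError(
                f"line {lineno}: expected 'tree category term', got {line!r}"
            )
        tree_name, category, term = fields
        factors = []
        multiplicity = 1
        for pos, tok in enumerate(term.split("*")):
            tok = tok.strip()
            if re.fullmatch(r"\d+", tok):
                if pos != 0:
                    raise EQNParseError(
                        f"line {lineno}: integer coefficient {tok!r} must lead the term"
                    )
                multiplicity = int(tok)
                continue
            m = _FACTOR_RE.match(tok)
            if not m:
                raise EQNParseError(
                    f"line {lineno}: malformed factor {tok!r} "
                    "(expected 'param' or '(1-param)')"
                )
            comp, direct = m.group(1), m.group(2)
            name = comp or direct
            factors.append((name, "complement" if comp else "direct"))
            if name not in params:
                params.append(name)
        t = trees.setdefault(tree_name, {"categories": [], "branches": []})
        if category not in t["categories"]:
            t["categories"].append(category)
        t["branches"].append(Branch(category, tuple(factors), multiplicity))

    model_trees = tuple(
        Tree(
            name=name,
            item_total_role=name,
            categories=tuple(t["categories"]),
            branches=tuple(t["branches"]),
        )
        for name, t in trees.items()
    )
    return MPTModel(name="eqn_model", parameters=tuple(params), trees=model_trees)


def enumerate_branches(body):
    for lineno, line in body:
        yield lineno, line


def render_eqn(model: MPTModel) -> str:
    """Render a model to canonical EQN text.

    Ordering is stable: trees in model order, branches grouped by the
    tree's category order, factors as stored.  ``parse_eqn(render_eqn(m))``
    is structurally equal to ``m``.
    """
    lines = [f"# {model.name}"]
    for tree in model.trees:
        order = {c: i for i, c in enumerate(tree.categories)}
        for b in sorted(tree.branches, key=lambda b: order[b.category]):
            toks = [] if b.multiplicity == 1 else [str(b.multiplicity)]
            toks += [
                name if pol == "direct" else f"(1-{name})" for name, pol in b.factors
            ]
            lines.append(f"{tree.name} {b.category} {'*'.join(toks)}")
    return "\n".join(lines) + "\n"
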