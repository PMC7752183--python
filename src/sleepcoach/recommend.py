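"""Rule-based sleep advice: generic hygiene and personalized bundles.

Screened-low users receive a fixed three-item hygiene bundle (keep a
regular wake time, get morning light, sleep in a quiet dark room).  Users
in the intervention receive a personalized bundle built from a declarative
rule table evaluated against the week's aggregated night indicators and
their latest ISI answers.

Rule conditions are written in a deliberately small expression grammar —
names, numeric literals, comparisons, ``and``/``or``/``not`` and basic
arithmetic — compiled through the ``ast`` module with a strict node
whitelist, so a rule file can never execute arbitrary code.  The default
rule set shipped with the package encodes standard behavioral
sleep-medicine heuristics (time-in-bed restriction when efficiency is low
and time in bed long, stimulus control when sleep onset latency is high, a
fixed rise time when terminal wakefulness is high, a wind-down routine when
the night is fragmented) and lives entirely in configuration, so a
deployment can swap in its own conditions without code change.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .diary import NightIndicators
from .instruments import ISIResponse, ISIResult

__all__ = [
    "RecommendationRule",
    "RuleSet",
    "AdviceItem",
    "AdviceBundle",
    "RuleConfigError",
    "compile_condition",
    "load_rules",
    "load_catalog",
    "default_rules",
    "default_catalog",
    "generic_hygiene",
    "personalize",
    "build_env",
    "HYGIENE_TEMPLATE_IDS",
]

HYGIENE_TEMPLATE_IDS = ("regular_wake_time", "morning_light", "quiet_dark_room")

#: names a rule condition may reference
_ENV_NAMES = frozenset(
    {"sol", "nwak", "twak", "waso", "tib", "tst", "se", "isi_total"}
    | {f"isi_item_{i}" for i in range(1, 8)}
)

_ALLOWED_NODES = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.USub,
    ast.BinOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Compare,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
    ast.Eq,
    ast.NotEq,
    ast.Name,
    ast.Load,
    ast.Constant,
)


class RuleConfigError(ValueError):
    """A malformed rule set (bad schema, duplicate id, bad condition)."""


def compile_condition(expr: str) -> Callable[[Mapping[str, float]], bool]:
    """Compile a condition expression into a predicate over an indicator env.

    Only comparisons, boolean algebra and +-*/ over whitelisted indicator
    names and numeric literals are accepted.
    """
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise RuleConfigError(f"unparseable condition {expr!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise RuleConfigError(
                f"condition {expr!r} uses disallowed construct {type(node).__name__}"
            )
        if isinstance(node, ast.Name) and node.id not in _ENV_NAMES:
            raise RuleConfigError(
                f"condition {expr!r} references unknown name {node.id!r}"
            )
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
            raise RuleConfigError(f"condition {expr!r} uses non-numeric literal")
    code = compile(tree, "<rule-condition>", "eval")

    def predicate(env: Mapping[str, float]) -> bool:
        return bool(eval(code, {"__builtins__": {}}, dict(env)))

    return predicate


@dataclass(frozen=True)
class RecommendationRule:
    id: str
    condition: str
    advice_template: str
    priority: int
    params: Tuple[Tuple[str, object], ...] = ()
    _predicate: Callable[[Mapping[str, float]], bool] = field(
        repr=False, compare=False, default=None
    )

    def fires(self, env: Mapping[str, float]) -> bool:
        return self._predicate(env)


@dataclass(frozen=True)
class RuleSet:
    rules: Tuple[RecommendationRule, ...]

    def __len__(self) -> int:
        return len(self.rules)


@dataclass(frozen=True)
class AdviceItem:
    advice_id: str
    rule_id: Optional[str] = None
    params: Tuple[Tuple[str, object], ...] = ()


@dataclass(frozen=True)
class AdviceBundle:
    items: Tuple[AdviceItem, ...]
    source: str  # "generic_hygiene" | "personalized"


def _as_document(source: Union[str, Path, Mapping]) -> Mapping:
    if isinstance(source, Mapping):
        return source
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))):
        with open(source, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(source)


def load_rules(source: Union[str, Path, Mapping]) -> RuleSet:
    """Load and validate a rule set from YAML/JSON text, a path or a dict."""
    doc = _as_document(source)
    if doc is None:
        doc = {}
    raw = doc.get("rules", doc if isinstance(doc, list) else [])
    if raw is None:
        raw = []
    if not isinstance(raw, list):
        raise RuleConfigError("rule document must contain a 'rules' list")
    rules: List[RecommendationRule] = []
    seen: set = set()
    for i, item in enumerate(raw):
        if not isinstance(item, Mapping):
            raise RuleConfigError(f"rule #{i + 1} is not a mapping")
        missing = [k for k in ("id", "when", "advice") if k not in item]
        if missing:
            raise RuleConfigError(
                f"rule #{i + 1} ({item.get('id', '?')}): missing field(s) {', '.join(missing)}"
            )
        rid = str(item["id"])
        if rid in seen:
            raise RuleConfigError(f"duplicate rule id {rid!r}")
        seen.add(rid)
        try:
            pred = compile_condition(str(item["when"]))
        except RuleConfigError as exc:
            raise RuleConfigError(f"rule {rid!r}: {exc}") from exc
        params = tuple(sorted((str(k), v) for k, v in (item.get("params") or {}).items()))
        rules.append(
            RecommendationRule(
                id=rid,
                condition=str(item["when"]),
                advice_template=str(item["advice"]),
                priority=int(item.get("priority", 100)),
                params=params,
                _predicate=pred,
            )
        )
    return RuleSet(rules=tuple(rules))


def load_catalog(source: Union[str, Path, Mapping]) -> Dict[str, str]:
    """Load the advice-id -> template-text catalog."""
    doc = _as_document(source)
    catalog = doc.get("advice", doc) if isinstance(doc, Mapping) else doc
    if not isinstance(catalog, Mapping):
        raise RuleConfigError("advice catalog must be a mapping of id -> template")
    return {str(k): str(v) for k, v in catalog.items()}


def _read_packaged(name: str) -> str:
    return resources.files("sleepcoach.data").joinpath(name).read_text(encoding="utf-8")


def default_rules() -> RuleSet:
    """The rule set shipped with the package (reconstruction of standard
    behavioral heuristics; replaceable via configuration)."""
    return load_rules(yaml.safe_load(_read_packaged("default_rules.yaml")))


def default_catalog() -> Dict[str, str]:
    return load_catalog(yaml.safe_load(_read_packaged("advice_catalog.yaml")))


def generic_hygiene() -> AdviceBundle:
    """The fixed three-item hygiene bundle given to screened-low users."""
    return AdviceBundle(
        items=tuple(AdviceItem(advice_id=t) for t in HYGIENE_TEMPLATE_IDS),
        source="generic_hygiene",
    )


def build_env(
    week: NightIndicators,
    isi_response: Optional[ISIResponse] = None,
    isi_result: Optional[ISIResult] = None,
) -> Dict[str, float]:
    """Evaluation environment for rule conditions from a weekly aggregate."""
    env: Dict[str, float] = {
        "sol": week.sol,
        "nwak": week.nwak,
        "twak": week.twak,
        "waso": week.waso,
        "tib": week.tib,
        "tst": week.tst,
        "se": week.se,
    }
    if isi_result is not None:
        env["isi_total"] = float(isi_result.total)
    elif isi_response is not None:
        env["isi_total"] = float(sum(isi_response.items))
    else:
        env["isi_total"] = 0.0
    items = isi_response.items if isi_response is not None else (0,) * 7
    for i, v in enumerate(items, start=1):
        env[f"isi_item_{i}"] = float(v)
    return env


def personalize(
    week: NightIndicators,
    isi_response: Optional[ISIResponse] = None,
    isi_result: Optional[ISIResult] = None,
    rules: Optional[RuleSet] = None,
) -> AdviceBundle:
    """Personalized advice bundle for the week's indicators and ISI answers.

    Every rule whose condition holds contributes one advice item; items are
    ordered by (priority, rule id) so the output is independent of rule-file
    order.  When no rule fires, the generic hygiene items are returned,
    marked as personalized output.
    """
    if rules is None:
        rules = default_rules()
    env = build_env(week, isi_response, isi_result)
    fired = sorted(
        (r for r in rules.rules if r.fires(env)), key=lambda r: (r.priority, r.id)
    )
    if not fired:
        return AdviceBundle(
            items=tuple(AdviceItem(advice_id=t) for t in HYGIENE_TEMPLATE_IDS),
            source="personalized",
        )
    return AdviceBundle(
        items=tuple(
            AdviceItem(advice_id=r.advice_template, rule_id=r.id, params=r.params)
            for r in fired
        ),
        source="personalized",
    )
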