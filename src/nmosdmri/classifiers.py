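"""Rule- and score-based NMOSD/MS classifiers over per-patient feature vectors.

Three families of classifier operate on the same input — a mapping from
``feature_id`` to 0/1 presence (NaN for "no relevant imaging") with lesion
counts under ``n_<key>`` names:

* fixed brain-MRI criteria (Paty, Barkhof) computed from lesion counts;
* the weighted NMOSD/MS summative score with the combination rule
  "NMOSD when NMOSD score x ratio strictly exceeds the MS score";
* a binary decision-tree engine and declarative boolean rulesets, both
  loaded from config files.

Missing features evaluate as absent inside every classifier; a patient who
lacks all the imaging a classifier depends on is unclassifiable (``None``)
and is dropped from that classifier's denominator downstream.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import yaml

from .catalog import FeatureCatalog, validate_feature_refs
from .cohort import TOTAL_T2_KEY

__all__ = [
    "paty",
    "barkhof",
    "ScoreModel",
    "score_classify",
    "load_score_model",
    "load_default_score_model",
    "DecisionNode",
    "tree_classify",
    "load_tree",
    "RuleSet",
    "external_criteria",
    "load_rulesets",
    "as_nmosd_classifier",
]

Features = Mapping[str, float]
Classifier = Callable[[Features], "str | None"]

#: Macro regions used by regional score mode.
_MACRO_REGION = {
    "optic_pathway": "optic",
    "brain_global": "brain",
    "supratentorial": "brain",
    "infratentorial": "brain",
    "spinal_cord": "cord",
}


def _count(features: Features, key: str) -> float:
    return features.get(f"n_{key}", float("nan"))


def _truthy(value) -> bool:
    """Presence test treating NaN/None (missing imaging) as absent."""
    if value is None:
        return False
    try:
        if math.isnan(value):
            return False
    except TypeError:
        pass
    return bool(value)


def paty(features: Features) -> bool | None:
    """Paty brain-MRI criteria.

    Met when the brain shows at least 3 white-matter lesions over 3 mm, or
    2 white-matter lesions of which at least one is periventricular.
    Returns ``None`` when no brain lesion counts are available.
    """
    wm = _count(features, TOTAL_T2_KEY)
    if math.isnan(wm):
        return None
    pv = _count(features, "periventricular_T2")
    pv = 0.0 if math.isnan(pv) else pv
    return wm >= 3 or (wm >= 2 and pv >= 1)


def barkhof(features: Features) -> bool | None:
    """Barkhof dissemination-in-space criteria.

    Met when at least three of the four conditions hold: (1) a Gd-enhancing
    lesion or 9+ T2 lesions, (2) at least 1 infratentorial lesion, (3) at
    least 1 juxtacortical lesion, (4) at least 3 periventricular lesions.
    """
    total = _count(features, TOTAL_T2_KEY)
    if math.isnan(total):
        return None

    def cnt(key: str) -> float:
        v = _count(features, key)
        return 0.0 if math.isnan(v) else v

    conditions = (
        _truthy(features.get("brain_gd")) or total >= 9,
        cnt("infratentorial_T2") >= 1,
        cnt("juxtacortical_T2") >= 1,
        cnt("periventricular_T2") >= 3,
    )
    return sum(conditions) >= 3


# --------------------------------------------------------------------- score


@dataclass
class ScoreModel:
    """Weighted binary-feature scores for NMOSD and MS.

    In summative mode each class score is the weighted sum of its present
    features.  In regional mode features are grouped into optic / brain /
    cord sub-scores and a region contributes to the class score only when
    its sub-score reaches the region's cut-off.  The combination rule labels
    a patient NMOSD when ``nmosd_score * combination_ratio > ms_score``
    (strict); ties go to MS.
    """

    nmosd_features: dict[str, int]
    ms_features: dict[str, int]
    combination_ratio: float = 3.5
    mode: str = "summative"
    region_cutoffs: dict[str, int] = field(default_factory=dict)
    _region_of: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("summative", "regional"):
            raise ValueError(f"unknown score mode {self.mode!r}")
        if self.combination_ratio <= 0:
            raise ValueError("combination ratio must be positive")
        overlap = set(self.nmosd_features) & set(self.ms_features)
        if overlap:
            raise ValueError(f"features in both class lists: {sorted(overlap)}")
        for fid, w in {**self.nmosd_features, **self.ms_features}.items():
            if w < 1:
                raise ValueError(f"weight for {fid!r} must be >= 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.nmosd_features) + list(self.ms_features)

    def validate(self, catalog: FeatureCatalog) -> "ScoreModel":
        unknown = validate_feature_refs(catalog, self.feature_ids)
        if unknown:
            raise ValueError(f"score model references unknown features: {unknown}")
        self._region_of = {
            fid: _MACRO_REGION[catalog.lookup(fid).region] for fid in self.feature_ids
        }
        return self

    def _class_score(self, features: Features, weights: dict[str, int]) -> float:
        if self.mode == "summative":
            return float(
                sum(w for fid, w in weights.items() if _truthy(features.get(fid)))
            )
        if not self._region_of:
            raise ValueError("regional mode requires validate(catalog) before scoring")
        by_region: dict[str, float] = {}
        for fid, w in weights.items():
            if _truthy(features.get(fid)):
                by_region[self._region_of[fid]] = by_region.get(self._region_of[fid], 0.0) + w
        total = 0.0
        for region, sub in by_region.items():
            if sub >= self.region_cutoffs.get(region, 0):
                total += sub
        return total

    def nmosd_score(self, features: Features) -> float:
        return self._class_score(features, self.nmosd_features)

    def ms_score(self, features: Features) -> float:
        return self._class_score(features, self.ms_features)

    def to_dict(self) -> dict:
        out = {
            "nmosd_features": dict(self.nmosd_features),
            "ms_features": dict(self.ms_features),
            "combination_ratio": self.combination_ratio,
            "mode": self.mode,
        }
        if self.region_cutoffs:
            out["region_cutoffs"] = dict(self.region_cutoffs)
        return out


def score_classify(
    features: Features, model: ScoreModel
) -> tuple[str | None, float, float]:
    """Apply the combination rule; returns ``(label, nmosd_score, ms_score)``.

    The label is ``None`` (unclassifiable) when every feature the model
    reads is missing, i.e. the patient has none of the relevant imaging.
    """
    values = [features[fid] for fid in model.feature_ids if fid in features]
    if values and all(isinstance(v, float) and math.isnan(v) for v in values):
        return None, float("nan"), float("nan")
    nmo = model.nmosd_score(features)
    ms = model.ms_score(features)
    label = "NMOSD" if nmo * model.combination_ratio > ms else "MS"
    return label, nmo, ms


def load_score_model(source: str | Path | Mapping, catalog: FeatureCatalog | None = None) -> ScoreModel:
    """Load a :class:`ScoreModel` from a YAML file or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    model = ScoreModel(
        nmosd_features={k: int(v) for k, v in source["nmosd_features"].items()},
        ms_features={k: int(v) for k, v in source["ms_features"].items()},
        combination_ratio=float(source.get("combination_ratio", 3.5)),
        mode=source.get("mode", "summative"),
        region_cutoffs={k: int(v) for k, v in source.get("region_cutoffs", {}).items()},
    )
    if catalog is not None:
        model.validate(catalog)
    return model


def load_default_score_model(catalog: FeatureCatalog | None = None) -> ScoreModel:
    """The package's default score model.

    Feature lists are the significantly associated features of each disease;
    double weight goes to longitudinally extensive cord and bilateral optic
    nerve lesions (NMOSD) and to ovoid lesions (MS).  The exact fitted
    weights of the original models are unpublished, so this default is a
    reconstruction and fully overridable by config.
    """
    from importlib import resources

    text = resources.files("nmosdmri.data").joinpath("default_score_model.yaml").read_text()
    return load_score_model(yaml.safe_load(text), catalog)


# ---------------------------------------------------------------------- tree


@dataclass(frozen=True)
class DecisionNode:
    """Internal test node or leaf of a binary decision tree.

    A node either carries ``leaf`` in {"NMOSD", "MS"} or a ``feature_id``
    with ``yes``/``no`` children.  Missing and absent features both follow
    the ``no`` branch.
    """

    leaf: str | None = None
    feature_id: str | None = None
    yes: "DecisionNode | None" = None
    no: "DecisionNode | None" = None

    def __post_init__(self) -> None:
        if self.leaf is not None:
            if self.leaf not in ("NMOSD", "MS"):
                raise ValueError(f"leaf label must be NMOSD or MS, got {self.leaf!r}")
            if self.feature_id is not None or self.yes is not None or self.no is not None:
                raise ValueError("leaf node cannot also test a feature")
        else:
            if self.feature_id is None or self.yes is None or self.no is None:
                raise ValueError("internal node needs feature_id, yes and no branches")

    def feature_ids(self) -> list[str]:
        if self.leaf is not None:
            return []
        return [self.feature_id] + self.yes.feature_ids() + self.no.feature_ids()

    @classmethod
    def from_dict(cls, obj) -> "DecisionNode":
        if isinstance(obj, str):
            return cls(leaf=obj)
        if not isinstance(obj, Mapping):
            raise ValueError(f"malformed tree node: {obj!r}")
        # YAML 1.1 reads bare yes:/no: keys as booleans; normalise them back
        obj = {("yes" if k is True else "no" if k is False else k): v for k, v in obj.items()}
        if "leaf" in obj:
            return cls(leaf=obj["leaf"])
        try:
            return cls(
                feature_id=obj["feature"],
                yes=cls.from_dict(obj["yes"]),
                no=cls.from_dict(obj["no"]),
            )
        except KeyError as exc:
            raise ValueError(f"malformed tree node, missing {exc}") from None


def tree_classify(features: Features, root: DecisionNode) -> str:
    node = root
    while node.leaf is None:
        node = node.yes if _truthy(features.get(node.feature_id)) else node.no
    return node.leaf


def load_tree(source: str | Path | Mapping, catalog: FeatureCatalog | None = None) -> DecisionNode:
    """Load a decision tree from a YAML file or nested mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    root = DecisionNode.from_dict(source)
    if catalog is not None:
        unknown = validate_feature_refs(catalog, root.feature_ids())
        if unknown:
            raise ValueError(f"tree references unknown features: {sorted(set(unknown))}")
    return root


def load_example_tree(catalog: FeatureCatalog | None = None) -> DecisionNode:
    """Illustrative decision tree shipped with the package.

    This tree demonstrates the engine on clinically sensible splits; it is
    not a fitted model.
    """
    from importlib import resources

    text = resources.files("nmosdmri.data").joinpath("example_tree.yaml").read_text()
    return load_tree(yaml.safe_load(text), catalog)


# ------------------------------------------------------------------ rulesets

_ALLOWED_AST = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.Name,
    ast.Load,
    ast.Constant,
)


@dataclass(frozen=True)
class RuleSet:
    """Declarative boolean rule over feature ids.

    The expression grammar is Python's ``and``/``or``/``not`` over feature
    names and the constants ``True``/``False``.  A record satisfying the
    expression is labelled NMOSD, otherwise MS (wrap the expression in
    ``not`` for MS-directed criteria).
    """

    name: str
    expression: str

    def __post_init__(self) -> None:
        self._compile()  # fail fast on malformed expressions

    def _compile(self) -> ast.Expression:
        tree = ast.parse(self.expression, mode="eval")
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED_AST):
                raise ValueError(
                    f"ruleset {self.name!r}: disallowed syntax {type(node).__name__}"
                )
            if isinstance(node, ast.Constant) and not isinstance(node.value, bool):
                raise ValueError(f"ruleset {self.name!r}: only True/False constants allowed")
        return tree

    def feature_ids(self) -> list[str]:
        return [
            n.id for n in ast.walk(self._compile()) if isinstance(n, ast.Name)
        ]

    def evaluate(self, features: Features) -> bool:
        def ev(node) -> bool:
            if isinstance(node, ast.Expression):
                return ev(node.body)
            if isinstance(node, ast.BoolOp):
                op = all if isinstance(node.op, ast.And) else any
                return op(ev(v) for v in node.values)
            if isinstance(node, ast.UnaryOp):
                return not ev(node.operand)
            if isinstance(node, ast.Name):
                return _truthy(features.get(node.id))
            if isinstance(node, ast.Constant):
                return bool(node.value)
            raise AssertionError("unreachable")

        return ev(self._compile())


def external_criteria(features: Features, ruleset: RuleSet) -> str:
    """Label a record NMOSD when the ruleset expression holds, else MS."""
    return "NMOSD" if ruleset.evaluate(features) else "MS"


def load_rulesets(source: str | Path | Mapping, catalog: FeatureCatalog | None = None) -> dict[str, RuleSet]:
    """Load named rulesets from a YAML mapping ``{name: expression}``."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    rules = {name: RuleSet(name, expr) for name, expr in source.items()}
    if catalog is not None:
        for rule in rules.values():
            unknown = validate_feature_refs(catalog, rule.feature_ids())
            if unknown:
                raise ValueError(
                    f"ruleset {rule.name!r} references unknown features: {sorted(set(unknown))}"
                )
    return rules


def as_nmosd_classifier(criterion: Callable[[Features], "bool | None"]) -> Classifier:
    """Turn an MS-directed brain criterion into an NMOSD/MS classifier.

    Criteria such as Paty and Barkhof detect MS-typical brain lesion
    patterns; as differential classifiers they predict NMOSD when the
    criterion is NOT met.  ``None`` (no relevant imaging) passes through.
    """

    def classify(features: Features) -> str | None:
        met = criterion(features)
        if met is None:
            return None
        return "MS" if met else "NMOSD"

    return classify
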