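"""JSON-serialisable axis-aligned decision trees over named features.

The deployed models are tiny (depth <= 3, two features each), so the tree is
stored as an explicit node list and traversed directly; scikit-learn is used
for *fitting* trees, after which the fitted structure is converted to this
representation.  Threshold semantics: ``value <= threshold`` goes left.

The three published model *templates* (their two-feature signatures) are
shipped without thresholds — thresholds must be learned on data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "DecisionTreeModel",
    "MissingFeatureError",
    "TASKS",
    "MODEL_TEMPLATES",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

TASKS = ("artifact", "preview_focus", "acquired_focus", "unspecified")

#: Two-feature signatures of the published best models, per task.
MODEL_TEMPLATES: dict[str, tuple[str, str]] = {
    "artifact": ("GLVA_SUM_DIFF", "PRCB_SUM_Y_BLUR"),
    "preview_focus": ("CURV_SUM_RATIO", "LAPV_MAX_GRAY"),
    "acquired_focus": ("PRCB_MEAN_Y_GRAY", "CURV_SUM_DIFF"),
}


class MissingFeatureError(KeyError):
    """A feature the model needs is absent or a NaN sentinel."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(f"missing or sentinel feature values: {self.names}")


@dataclass
class DecisionTreeModel:
    """Axis-aligned tree over named features.

    ``nodes[0]`` is the root.  Internal nodes are
    ``{"feature": str, "threshold": float, "left": int, "right": int}``;
    leaves are ``{"label": str, "scores": {class: probability}}``.
    """

    nodes: list[dict]
    classes: list[str]
    task: str = "unspecified"
    max_depth: int = 3
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if not self.nodes:
            raise ValueError("tree must have at least one node")
        if self.depth() > self.max_depth:
            raise ValueError(f"tree depth {self.depth()} exceeds max_depth {self.max_depth}")

    # -------------------------------------------------------------- queries

    def feature_names_used(self) -> list[str]:
        return sorted({n["feature"] for n in self.nodes if "feature" in n})

    def depth(self, index: int = 0) -> int:
        node = self.nodes[index]
        if "label" in node:
            return 0
        return 1 + max(self.depth(node["left"]), self.depth(node["right"]))

    # ----------------------------------------------------------- prediction

    def predict_one(self, features: Mapping[str, float]) -> tuple[str, dict[str, float]]:
        """Root-to-leaf traversal; returns (label, class scores)."""
        needed = self.feature_names_used()
        bad = [
            n
            for n in needed
            if n not in features or features[n] is None or np.isnan(features[n])
        ]
        if bad:
            raise MissingFeatureError(bad)
        node = self.nodes[0]
        while "label" not in node:
            branch = "left" if features[node["feature"]] <= node["threshold"] else "right"
            node = self.nodes[node[branch]]
        return node["label"], dict(node["scores"])

    def predict(self, table) -> list[str]:
        """Predict labels for a DataFrame / sequence of feature mappings."""
        rows = (
            (row for _, row in table.iterrows()) if hasattr(table, "iterrows") else iter(table)
        )
        return [self.predict_one(row)[0] for row in rows]

    # -------------------------------------------------------- serialisation

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "task": self.task,
            "classes": list(self.classes),
            "max_depth": self.max_depth,
            "feature_names_used": self.feature_names_used(),
            "nodes": self.nodes,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTreeModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {d.get('schema_version')!r}")
        return cls(
            nodes=d["nodes"],
            classes=list(d["classes"]),
            task=d["task"],
            max_depth=d["max_depth"],
            metadata=d.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "DecisionTreeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # ------------------------------------------------------------- builders

    @classmethod
    def from_sklearn(
        cls,
        estimator,
        feature_names: list[str],
        *,
        task: str = "unspecified",
        metadata: dict | None = None,
    ) -> "DecisionTreeModel":
        """Convert a fitted sklearn ``DecisionTreeClassifier``."""
        t = estimator.tree_
        classes = [str(c) for c in estimator.classes_]
        nodes: list[dict] = [None] * t.node_count  # type: ignore[list-item]
        for i in range(t.node_count):
            if t.children_left[i] == -1:  # leaf
                counts = t.value[i][0]
                total = counts.sum()
                scores = {c: float(v) / total for c, v in zip(classes, counts)}
                label = classes[int(np.argmax(counts))]
                nodes[i] = {"label": label, "scores": scores}
            else:
                nodes[i] = {
                    "feature": feature_names[t.feature[i]],
                    "threshold": float(t.threshold[i]),
                    "left": int(t.children_left[i]),
                    "right": int(t.children_right[i]),
                }
        return cls(
            nodes=nodes,
            classes=classes,
            task=task,
            max_depth=max(int(estimator.get_depth()), 1),
            metadata=metadata or {},
        )
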