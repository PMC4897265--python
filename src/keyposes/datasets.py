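"""On-disk dataset layout and feature extraction helpers.

The standard layout is one image per frame::

    <root>/<class>/<actor>/<sequence>/<view>/frame_00001.png

plus a ``manifest.json`` at the root listing classes, views, actors and
sequences.  ``load_mask_dataset`` reads either the manifest or, absent
one, walks the directory tree.  Any nonzero pixel is foreground.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .features import RadialFeatureConfig, load_mask, pose_feature
from .model import LabeledFeatureSequence
from .synthetic import MaskDataset, MultiviewMaskSequence, SynthConfig

MANIFEST_NAME = "manifest.json"


def write_mask_dataset(dataset: MaskDataset, root) -> None:
    """Write a mask dataset in the standard layout with a manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for seq in dataset.sequences:
        for view, frames in seq.views.items():
            d = root / seq.action_class / seq.actor / seq.sequence_id / view
            d.mkdir(parents=True, exist_ok=True)
            for i, mask in enumerate(frames):
                img = Image.fromarray(np.where(mask, 255, 0).astype(np.uint8))
                img.save(d / f"frame_{i + 1:05d}.png")
        entries.append(
            {
                "action_class": seq.action_class,
                "actor": seq.actor,
                "sequence_id": seq.sequence_id,
                "views": sorted(seq.views),
            }
        )
    manifest = {
        "classes": dataset.classes,
        "views": dataset.views,
        "actors": dataset.actors,
        "sequences": entries,
    }
    (root / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _frames_in(view_dir: Path) -> list[np.ndarray]:
    paths = sorted(p for p in view_dir.iterdir() if p.suffix.lower() in (".png", ".pgm"))
    return [load_mask(p) for p in paths]


def load_mask_dataset(root) -> MaskDataset:
    """Load a dataset in the standard layout (manifest-driven if present)."""
    root = Path(root)
    manifest_path = root / MANIFEST_NAME
    sequences: list[MultiviewMaskSequence] = []
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        for entry in manifest["sequences"]:
            seq_dir = root / entry["action_class"] / entry["actor"] / entry["sequence_id"]
            views = {v: _frames_in(seq_dir / v) for v in entry["views"]}
            sequences.append(MultiviewMaskSequence(
                action_class=entry["action_class"],
                actor=entry["actor"],
                sequence_id=entry["sequence_id"],
                views=views,
            ))
        classes = manifest["classes"]
        view_names = manifest["views"]
        actors = manifest["actors"]
    else:
        for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for actor_dir in sorted(p for p in cls_dir.iterdir() if p.is_dir()):
                for seq_dir in sorted(p for p in actor_dir.iterdir() if p.is_dir()):
                    views = {
                        v.name: _frames_in(v)
                        for v in sorted(p for p in seq_dir.iterdir() if p.is_dir())
                    }
                    sequences.append(MultiviewMaskSequence(
                        action_class=cls_dir.name,
                        actor=actor_dir.name,
                        sequence_id=seq_dir.name,
                        views=views,
                    ))
        classes = sorted({s.action_class for s in sequences})
        view_names = sorted({v for s in sequences for v in s.views})
        actors = sorted({s.actor for s in sequences})
    if not sequences:
        raise ValueError(f"no sequences found under {root}")
    cfg = SynthConfig(
        n_classes=len(classes), n_views=len(view_names), n_actors=len(actors)
    )
    return MaskDataset(
        config=cfg, classes=classes, views=view_names, actors=actors,
        sequences=sequences,
    )


# ---------------------------------------------------------------------------
# feature extraction over whole datasets
# ---------------------------------------------------------------------------

class MultiviewFeatureSequence:
    """A multiview sequence with per-view (T, S) frame-feature arrays."""

    def __init__(self, action_class, actor, sequence_id, views):
        self.action_class = action_class
        self.actor = actor
        self.sequence_id = sequence_id
        self.views: dict[str, np.ndarray] = views


class FeatureDataset:
    def __init__(self, classes, views, actors, sequences, feature_config):
        self.classes = list(classes)
        self.views = list(views)
        self.actors = list(actors)
        self.sequences: list[MultiviewFeatureSequence] = list(sequences)
        self.feature_config = feature_config

    def __len__(self) -> int:
        return len(self.sequences)


def extract_features(dataset: MaskDataset, cfg: RadialFeatureConfig) -> FeatureDataset:
    """Compute the radial descriptor for every frame of every view stream."""
    out = []
    for seq in dataset.sequences:
        views = {
            view: np.stack([pose_feature(m, cfg).values for m in frames])
            for view, frames in seq.views.items()
        }
        out.append(MultiviewFeatureSequence(
            action_class=seq.action_class,
            actor=seq.actor,
            sequence_id=seq.sequence_id,
            views=views,
        ))
    return FeatureDataset(
        classes=dataset.classes, views=dataset.views, actors=dataset.actors,
        sequences=out, feature_config=cfg,
    )


def to_labeled_sequences(
    sequences: list[MultiviewFeatureSequence],
) -> list[LabeledFeatureSequence]:
    """Flatten multiview records into one training sequence per view stream."""
    out = []
    for seq in sequences:
        for view in sorted(seq.views):
            out.append(LabeledFeatureSequence(
                frames=seq.views[view],
                action_class=seq.action_class,
                view=view,
                actor=seq.actor,
                sequence_id=seq.sequence_id,
            ))
    return out
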