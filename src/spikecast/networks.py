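"""The Siamese feature extractor and the two comparative heads.

One shared-parameter extractor maps an IWC (head image + weather window)
to a 256-d feature vector:

* image branch: a backbone emits a 1000-d vector (ImageNet classifier
  head convention) which an affine map + ReLU reduces to 512;
* weather branch: a GRU consumes the T x 6 window oldest-first and its
  final 512-d hidden state is the weather feature;
* fusion: the concatenated 1024-d vector passes through FC1 -> ReLU ->
  FC2 to 256 dimensions.

Two comparative heads score an ordered pair of 256-d features:

* FC head: the 512-d concatenation through four fully connected layers
  (512 -> 256 -> 128 -> 64 -> classes) with ReLU between;
* TF head: the two vectors form a 2-token sequence (no embedding, no
  positional encoding) through one transformer block (4-head
  self-attention + residual, feed-forward + residual), token-wise
  max-pooling, and a dense classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import ValidationError
from .nn import Tensor

#: image preprocessing constants: pixels are scaled to [0,1] then
#: normalised per channel with these mean/sd values
IMAGE_NORM_MEAN = 0.5
IMAGE_NORM_SD = 0.5


@dataclass
class FeatureExtractorSpec:
    backbone_name: str = "tiny_cnn"
    backbone_out_dim: int = 1000
    image_proj_dim: int = 512
    weather_hidden_dim: int = 512
    fused_dim: int = 1024
    out_dim: int = 256
    image_size: int = 32
    weather_input_dim: int = 6

    def __post_init__(self):
        if self.fused_dim != self.image_proj_dim + self.weather_hidden_dim:
            raise ValidationError(
                "fused_dim must equal image_proj_dim + weather_hidden_dim"
            )
        if self.out_dim >= self.fused_dim:
            raise ValidationError("out_dim must be smaller than fused_dim")


@dataclass
class ComparativeSpec:
    head_type: str = "fc"  # {"fc", "tf"}
    in_dim: int = 512
    n_classes: int = 2
    fc_layers: int = 4
    attn_heads: int = 4

    def __post_init__(self):
        if self.head_type not in ("fc", "tf"):
            raise ValidationError(f"unknown head type {self.head_type!r}")
        if self.n_classes not in (2, 3):
            raise ValidationError("n_classes must be 2 or 3")


def preprocess_images(images: np.ndarray) -> np.ndarray:
    """uint8 (B, H, W, 3) -> float32 (B, 3, H, W) normalised to [-1, 1]."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    x = (x - IMAGE_NORM_MEAN) / IMAGE_NORM_SD
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


class ImageBranch(nn.Module):
    """Backbone (-> 1000-d) followed by a trainable affine + ReLU to 512."""

    def __init__(self, spec: FeatureExtractorSpec, rng: np.random.Generator,
                 backbone: nn.Module | None = None):
        self.spec = spec
        if backbone is not None:
            self.backbone = backbone
        elif spec.backbone_name == "tiny_cnn":
            self.backbone = nn.TinyCNNBackbone(rng)
        else:
            raise ValidationError(
                f"backbone {spec.backbone_name!r} requires an explicit module "
                "(plug-in contract: any callable image -> "
                f"{spec.backbone_out_dim}-d vector)"
            )
        self.proj = nn.Linear(spec.backbone_out_dim, spec.image_proj_dim, rng)

    def __call__(self, images: Tensor) -> Tensor:
        feats = self.backbone(images)
        if feats.shape[-1] != self.spec.backbone_out_dim:
            raise ValidationError(
                f"backbone produced {feats.shape[-1]}-d output, expected "
                f"{self.spec.backbone_out_dim} (plug-in contract violation)"
            )
        return self.proj(feats).relu()


class WeatherBranch(nn.Module):
    """GRU over the weather window; the final hidden state is the feature."""

    def __init__(self, spec: FeatureExtractorSpec, rng: np.random.Generator):
        self.spec = spec
        self.gru = nn.GRU(spec.weather_input_dim, spec.weather_hidden_dim, rng)

    def __call__(self, windows: Tensor) -> Tensor:
        if windows.shape[-1] != self.spec.weather_input_dim:
            raise ValidationError(
                f"weather window has {windows.shape[-1]} columns, expected "
                f"{self.spec.weather_input_dim}"
            )
        return self.gru(windows)


class FeatureExtractor(nn.Module):
    """Shared-parameter IWC encoder producing 256-d fused features."""

    def __init__(self, spec: FeatureExtractorSpec, rng: np.random.Generator,
                 backbone: nn.Module | None = None, zero_weather: bool = False):
        self.spec = spec
        self.zero_weather = zero_weather
        self.image_branch = ImageBranch(spec, rng, backbone)
        self.weather_branch = WeatherBranch(spec, rng)
        mid = spec.fused_dim // 2
        self.fc1 = nn.Linear(spec.fused_dim, mid, rng)
        self.fc2 = nn.Linear(mid, spec.out_dim, rng)

    def fuse(self, image_feat: Tensor, weather_feat: Tensor) -> Tensor:
        fused = nn.concat([image_feat, weather_feat], axis=-1)
        assert fused.shape[-1] == self.spec.fused_dim
        return self.fc2(self.fc1(fused).relu())

    def __call__(self, images: Tensor, windows: Tensor) -> Tensor:
        img = self.image_branch(images)
        if self.zero_weather:
            windows = Tensor(np.zeros_like(windows.data))
        wx = self.weather_branch(windows)
        return self.fuse(img, wx)

    def forward_dedup(
        self, images: Tensor, unique_windows: Tensor, window_idx: np.ndarray
    ) -> Tensor:
        """Run the GRU once per unique window, then gather per sample.

        Weather windows depend only on (field, imaging date), so a batch
        of IWCs typically shares far fewer distinct windows than samples.
        """
        img = self.image_branch(images)
        if self.zero_weather:
            unique_windows = Tensor(np.zeros_like(unique_windows.data))
        wx_u = self.weather_branch(unique_windows)
        wx = wx_u.index_select(window_idx)
        return self.fuse(img, wx)


class FCComparativeHead(nn.Module):
    """Four fully connected layers halving the width, ReLU between."""

    def __init__(self, spec: ComparativeSpec, rng: np.random.Generator):
        self.spec = spec
        widths = [spec.in_dim]
        for _ in range(spec.fc_layers - 1):
            widths.append(widths[-1] // 2)
        widths.append(spec.n_classes)
        self.layers = [
            nn.Linear(widths[i], widths[i + 1], rng) for i in range(len(widths) - 1)
        ]

    def __call__(self, v1: Tensor, v2: Tensor) -> Tensor:
        x = nn.concat([v1, v2], axis=-1)
        if x.shape[-1] != self.spec.in_dim:
            raise ValidationError(
                f"comparative head expects {self.spec.in_dim}-d input, "
                f"got {x.shape[-1]}"
            )
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


class TFComparativeHead(nn.Module):
    """One transformer block over the 2-token (first, second) sequence.

    No embedding layer and no positional encoding (the inputs are
    already continuous vectors).  The block output is flattened to 512
    dimensions and reduced by 1-D max-pooling (kernel 2, stride 2) to a
    256-d vector before the dense classifier.  Pooling along the
    feature axis — rather than across tokens — keeps the head sensitive
    to which vector is first and which is second: attention alone is
    permutation-equivariant, and a token-axis pool would make the head
    blind to operand order, which the asymmetric pair labels require.
    The pooled representation is symmetric exactly when the two inputs
    coincide.
    """

    def __init__(self, spec: ComparativeSpec, rng: np.random.Generator):
        self.spec = spec
        dim = spec.in_dim // 2
        self.dim = dim
        self.attn = nn.MultiHeadSelfAttention(dim, spec.attn_heads, rng)
        self.ff1 = nn.Linear(dim, 4 * dim, rng)
        self.ff2 = nn.Linear(4 * dim, dim, rng)
        self.classifier = nn.Linear(dim, spec.n_classes, rng)

    def __call__(self, v1: Tensor, v2: Tensor) -> Tensor:
        if v1.shape[-1] != self.dim or v2.shape[-1] != self.dim:
            raise ValidationError(
                f"TF head expects two {self.dim}-d vectors, got "
                f"{v1.shape[-1]} and {v2.shape[-1]}"
            )
        x = nn.stack([v1, v2], axis=1)  # (B, 2, dim)
        x = x + self.attn(x)
        B = x.shape[0]
        flat = x.reshape(B * 2, self.dim)
        ff = self.ff2(self.ff1(flat).relu()).reshape(B, 2, self.dim)
        x = x + ff
        # flatten the pair, then 1-D max-pool (kernel 2, stride 2)
        pooled = x.reshape(B, 2 * self.dim).reshape(B, self.dim, 2).max(axis=-1)
        return self.classifier(pooled)


def build_head(spec: ComparativeSpec, rng: np.random.Generator) -> nn.Module:
    if spec.head_type == "fc":
        return FCComparativeHead(spec, rng)
    return TFComparativeHead(spec, rng)


class SiameseComparator(nn.Module):
    """Extractor + comparative head bundle with its preprocessing state."""

    def __init__(
        self,
        fe_spec: FeatureExtractorSpec | None = None,
        comp_spec: ComparativeSpec | None = None,
        seed: int = 0,
        backbone: nn.Module | None = None,
        zero_weather: bool = False,
    ):
        self.fe_spec = fe_spec or FeatureExtractorSpec()
        self.comp_spec = comp_spec or ComparativeSpec()
        if self.comp_spec.in_dim != 2 * self.fe_spec.out_dim:
            raise ValidationError("head in_dim must be twice the extractor out_dim")
        rng = np.random.Generator(np.random.PCG64(seed))
        self.extractor = FeatureExtractor(
            self.fe_spec, rng, backbone, zero_weather=zero_weather
        )
        self.head = build_head(self.comp_spec, rng)
        self.window_stats = None  # set by the trainer

    # -- inference helpers ----------------------------------------------------
    def extract_arrays(
        self, images: np.ndarray, windows: np.ndarray
    ) -> np.ndarray:
        """Features for raw uint8 images and already-normalised windows."""
        with nn.no_grad():
            out = self.extractor(
                Tensor(preprocess_images(images)), Tensor(windows)
            )
        return out.data

    def extract_pool(
        self,
        images: np.ndarray,
        unique_windows: np.ndarray,
        window_idx: np.ndarray,
        batch_size: int = 512,
    ) -> np.ndarray:
        """Batched feature extraction with the GRU run once per window.

        ``images`` are raw uint8 (N, H, W, 3); ``unique_windows`` are
        normalised (K, T, 6) with ``window_idx`` mapping each image to
        its window.
        """
        with nn.no_grad():
            if self.extractor.zero_weather:
                unique_windows = np.zeros_like(unique_windows)
            wx_u = self.extractor.weather_branch(Tensor(unique_windows)).data
            out = np.empty((len(images), self.fe_spec.out_dim), dtype=np.float32)
            for lo in range(0, len(images), batch_size):
                sl = slice(lo, lo + batch_size)
                img = self.extractor.image_branch(
                    Tensor(preprocess_images(images[sl]))
                )
                wx = Tensor(wx_u[window_idx[sl]])
                out[sl] = self.extractor.fuse(img, wx).data
        return out

    def compare_features(self, v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
        """Class scores for ordered feature pairs (first, second)."""
        with nn.no_grad():
            logits = self.head(Tensor(np.atleast_2d(v1)), Tensor(np.atleast_2d(v2)))
        return logits.data


def save_checkpoint(model: SiameseComparator, path) -> None:
    """Self-describing checkpoint: parameters + spec JSON + window stats."""
    meta = {
        "fe_spec": asdict(model.fe_spec),
        "comp_spec": asdict(model.comp_spec),
        "zero_weather": model.extractor.zero_weather,
    }
    arrays = {f"param/{k}": v for k, v in model.state().items()}
    if model.window_stats is not None:
        arrays["stats/mean"] = model.window_stats.mean
        arrays["stats/sd"] = model.window_stats.sd
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> SiameseComparator:
    from .weather import WindowStats

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = SiameseComparator(
            FeatureExtractorSpec(**meta["fe_spec"]),
            ComparativeSpec(**meta["comp_spec"]),
            zero_weather=meta["zero_weather"],
        )
        state = {
            k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")
        }
        model.load_state(state)
        if "stats/mean" in data.files:
            model.window_stats = WindowStats(data["stats/mean"], data["stats/sd"])
    return model
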