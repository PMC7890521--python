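"""Saliency network assembly, training, stimulus embedding and recording.

The network maps a 320x240 RGB image (values in [0, 1]) to a single-channel
saliency map of the same size.  Architecture files (YAML) declare an ordered
sequence of conv / relu / maxpool / deconv layers; two bundled files,
``reference`` (full scale, 96 first-layer channels) and ``tiny`` (32x24
canvas for fast experiments), live under :mod:`salrsa.specs`.

Training minimises the Euclidean loss between the network output and a
ground-truth fixation map using Adam, with the batch order reshuffled each
epoch from the run seed.  ``forward_record`` exposes every recording point —
each convolution both before and after its ReLU, each pooling stage and the
deconvolution output — as a named activation tensor, the unit population
that the representational analysis consumes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import h5py
import numpy as np
import yaml
from sklearn.base import BaseEstimator

from .layers import Conv2D, MaxPool2D, ReLU, TransposedConv2D

__all__ = [
    "ActivationTensor",
    "NetworkSpec",
    "TrainingConfig",
    "Network",
    "SaliencyNetwork",
    "build_network",
    "forward_record",
    "train",
    "embed_stimulus",
    "embed_on_canvas",
    "save_weights",
    "load_weights",
]

CANVAS_WIDTH = 320
CANVAS_HEIGHT = 240
STIMULUS_SIZE = 256
CROP_ROWS = 8
GRAY = 0.5


@dataclass
class ActivationTensor:
    """Model-neuron activations of one layer for one stimulus.

    ``values`` is stored (height, width, channels); ``values[y, x, c]`` is
    the model neuron at spatial location (x, y) of channel c.
    """

    values: np.ndarray
    layer_id: str
    stimulus_id: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("activation values must be (H, W, C)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite activations in {self.layer_id}")

    def flatten(self) -> np.ndarray:
        """All model neurons of the layer as one pattern vector."""
        return self.values.ravel()


class SpecError(ValueError):
    """Inconsistent network architecture description."""


@dataclass
class TrainingConfig:
    learning_rate: float = 5.0e-5
    batch_size: int = 20
    epochs: int = 250
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")


class NetworkSpec:
    """Ordered layer descriptors plus input canvas dimensions."""

    def __init__(self, name: str, input_shape: tuple[int, int, int],
                 layers: list[dict]):
        self.name = name
        self.input_shape = tuple(input_shape)  # (width, height, channels)
        self.layers = [dict(d) for d in layers]
        self.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        inp = d["input"]
        return cls(d.get("name", "unnamed"),
                   (inp["width"], inp["height"], inp["channels"]),
                   d["layers"])

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def bundled(cls, name: str) -> "NetworkSpec":
        """Load a spec shipped with the package ('reference' or 'tiny')."""
        ref = importlib.resources.files("salrsa") / "specs" / f"{name}.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    def validate(self) -> None:
        w, h, c = self.input_shape
        if min(w, h, c) < 1:
            raise SpecError("input dims must be positive")
        seen = set()
        channels = c
        for d in self.layers:
            kind = d.get("kind")
            name = d.get("name")
            if kind not in {"conv", "relu", "maxpool", "deconv"}:
                raise SpecError(f"unknown layer kind {kind!r}")
            if name in seen:
                raise SpecError(f"duplicate layer name {name!r}")
            seen.add(name)
            if kind == "conv":
                if d["kernel"] % 2 == 0:
                    raise SpecError(f"conv {name}: kernel must be odd")
                channels = int(d["channels"])
            elif kind == "deconv":
                channels = int(d["channels"])
        w_out, h_out, _ = self.shape_schedule()[-1][1]
        if (w_out, h_out) != (w, h):
            raise SpecError(
                f"output dims {w_out}x{h_out} do not match canvas {w}x{h}")

    def counts(self) -> dict[str, int]:
        out = {"conv": 0, "relu": 0, "maxpool": 0, "deconv": 0}
        for d in self.layers:
            out[d["kind"]] += 1
        return out

    def pool_factor(self) -> int:
        f = 1
        for d in self.layers:
            if d["kind"] == "maxpool":
                f *= int(d["stride"])
        return f

    def shape_schedule(self) -> list[tuple[str, tuple[int, int, int]]]:
        """(layer name, (width, height, channels)) after every layer."""
        w, h, c = self.input_shape
        out = []
        for d in self.layers:
            kind = d["kind"]
            if kind == "conv":
                c = int(d["channels"])
            elif kind == "maxpool":
                k, s = int(d["kernel"]), int(d["stride"])
                if k > w or k > h:
                    raise SpecError(f"pool {d['name']}: kernel exceeds input")
                w = (w - k) // s + 1
                h = (h - k) // s + 1
            elif kind == "deconv":
                s = int(d["stride"])
                w, h, c = w * s, h * s, int(d["channels"])
            out.append((d["name"], (w, h, c)))
        return out


class Network:
    """An assembled network: named layers plus its spec."""

    def __init__(self, spec: NetworkSpec, layers: list[tuple[str, object]]):
        self.spec = spec
        self.layers = layers  # list of (name, layer object)

    def forward(self, x: np.ndarray, train: bool = False,
                record: bool = False):
        """Run a batch (N, H, W, C) through the network.

        Returns the output batch, or ``(output, records)`` when recording,
        where ``records`` maps layer name to the full batch activation.
        """
        records = {} if record else None
        for name, layer in self.layers:
            x = layer.forward(x, train=train)
            if record:
                records[name] = x
        return (x, records) if record else x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def parameters(self):
        for name, layer in self.layers:
            if getattr(layer, "has_params", False):
                for pname, value, grad in layer.params():
                    yield f"{name}.{pname}", value, grad

    def predict_map(self, image: np.ndarray, clip: bool = True) -> np.ndarray:
        """Saliency map (H, W) for one image (H, W, 3)."""
        out = self.forward(image[None])[0, :, :, 0]
        return np.clip(out, 0.0, 1.0) if clip else out

    def recording_points(self) -> list[str]:
        return [name for name, _ in self.layers]


def build_network(spec: NetworkSpec, seed: int, use_bias: bool = True) -> Network:
    """Randomly initialise a network from its spec.

    Filters are drawn zero-mean uniform scaled by fan-in
    (limit ``sqrt(3 / fan_in)``, unit-variance-over-fan-in); biases start at
    zero.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, object]] = []
    c_in = spec.input_shape[2]
    for d in spec.layers:
        kind, name = d["kind"], d["name"]
        if kind == "conv":
            k, c_out = int(d["kernel"]), int(d["channels"])
            fan_in = k * k * c_in
            limit = np.sqrt(3.0 / fan_in)
            w = rng.uniform(-limit, limit, size=(k, k, c_in, c_out))
            b = np.zeros(c_out) if use_bias else None
            layers.append((name, Conv2D(w, b)))
            c_in = c_out
        elif kind == "relu":
            layers.append((name, ReLU()))
        elif kind == "maxpool":
            layers.append((name, MaxPool2D(int(d["kernel"]), int(d["stride"]))))
        elif kind == "deconv":
            k, s, c_out = int(d["kernel"]), int(d["stride"]), int(d["channels"])
            fan_in = k * k * c_in
            limit = np.sqrt(3.0 / fan_in)
            w = rng.uniform(-limit, limit, size=(k, k, c_in, c_out))
            b = np.zeros(c_out) if use_bias else None
            layers.append((name, TransposedConv2D(w, stride=s, bias=b)))
            c_in = c_out
    return Network(spec, layers)


def forward_record(net: Network, stimulus: np.ndarray,
                   stimulus_id: int | None = None) -> dict[str, ActivationTensor]:
    """Record activations at every layer for one stimulus.

    Pre-ReLU convolution outputs and post-ReLU outputs appear under
    distinct layer ids (e.g. ``layer5`` and ``layer5_relu``).
    """
    stimulus = np.asarray(stimulus, dtype=np.float64)
    w, h, c = net.spec.input_shape
    if stimulus.shape != (h, w, c):
        raise ValueError(
            f"stimulus shape {stimulus.shape} does not match canvas "
            f"({h}, {w}, {c})")
    if stimulus.min() < 0 or stimulus.max() > 1:
        raise ValueError("stimulus values must lie in [0, 1]")
    _, recs = net.forward(stimulus[None], record=True)
    return {
        name: ActivationTensor(batch[0], layer_id=name, stimulus_id=stimulus_id)
        for name, batch in recs.items()
    }


class _Adam:
    def __init__(self, cfg: TrainingConfig):
        self.cfg = cfg
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params):
        c = self.cfg
        self.t += 1
        for name, value, grad in params:
            if name not in self.m:
                self.m[name] = np.zeros_like(value)
                self.v[name] = np.zeros_like(value)
            m = self.m[name]
            v = self.v[name]
            m *= c.beta1
            m += (1 - c.beta1) * grad
            v *= c.beta2
            v += (1 - c.beta2) * grad * grad
            mhat = m / (1 - c.beta1 ** self.t)
            vhat = v / (1 - c.beta2 ** self.t)
            value -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)


def euclidean_loss(output: np.ndarray, target: np.ndarray):
    """0.5 * sum of squared differences per sample, averaged over the batch.

    Returns ``(loss, grad_wrt_output)``.
    """
    diff = output - target
    n = output.shape[0]
    loss = 0.5 * float(np.sum(diff * diff)) / n
    return loss, diff / n


def train(net: Network, pairs, cfg: TrainingConfig | None = None,
          checkpoints=(), on_checkpoint=None) -> list[float]:
    """Train the network on (image, ground-truth map) pairs with Adam.

    ``pairs`` is a sequence of ``(image (H, W, 3), map (H, W))`` with map
    values in [0, 1].  Batch order is reshuffled each epoch from the run
    seed.  ``checkpoints`` is an iterable of epoch numbers after which
    ``on_checkpoint(epoch, net)`` is invoked (e.g. to record a partially
    trained model).  Returns the per-epoch mean loss history.
    """
    cfg = cfg or TrainingConfig()
    pairs = list(pairs)
    if not pairs:
        raise ValueError("training set is empty")
    images = np.stack([np.asarray(im, dtype=np.float64) for im, _ in pairs])
    maps = np.stack([np.asarray(mp, dtype=np.float64) for _, mp in pairs])
    if maps.min() < 0 or maps.max() > 1:
        raise ValueError("ground-truth maps must lie in [0, 1]")
    w, h, c = net.spec.input_shape
    if images.shape[1:] != (h, w, c) or maps.shape[1:] != (h, w):
        raise ValueError("training pair dims do not match the network canvas")
    maps = maps[..., None]  # single output channel
    rng = np.random.default_rng(cfg.seed)
    optim = _Adam(cfg)
    checkpoints = set(int(e) for e in checkpoints)
    history: list[float] = []
    n = len(pairs)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            out = net.forward(images[idx], train=True)
            loss, grad = euclidean_loss(out, maps[idx])
            net.backward(grad)
            optim.step(net.parameters())
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if epoch in checkpoints and on_checkpoint is not None:
            on_checkpoint(epoch, net)
    return history


def embed_stimulus(stimulus: np.ndarray) -> np.ndarray:
    """Embed a 256x256 RGB stimulus on the 320x240 gray canvas.

    Eight pixel rows are removed from the top and bottom of the stimulus
    and the remaining 256x240 block is centred horizontally on a canvas of
    uniform intensity 0.5, leaving 32 gray columns on each side.
    """
    stimulus = np.asarray(stimulus, dtype=np.float64)
    if stimulus.shape != (STIMULUS_SIZE, STIMULUS_SIZE, 3):
        raise ValueError(
            f"stimulus must be ({STIMULUS_SIZE}, {STIMULUS_SIZE}, 3), "
            f"got {stimulus.shape}")
    if stimulus.min() < 0 or stimulus.max() > 1:
        raise ValueError("stimulus values must lie in [0, 1]")
    cropped = stimulus[CROP_ROWS:STIMULUS_SIZE - CROP_ROWS]
    return embed_on_canvas(cropped, (CANVAS_WIDTH, CANVAS_HEIGHT))


def embed_on_canvas(image: np.ndarray, canvas_wh: tuple[int, int],
                    background: float = GRAY) -> np.ndarray:
    """Centre an RGB image on a uniform canvas (cropping if oversized)."""
    image = np.asarray(image, dtype=np.float64)
    cw, ch = canvas_wh
    h, w = image.shape[:2]
    if h > ch:
        top = (h - ch) // 2
        image = image[top:top + ch]
        h = ch
    if w > cw:
        left = (w - cw) // 2
        image = image[:, left:left + cw]
        w = cw
    canvas = np.full((ch, cw, 3), background, dtype=np.float64)
    top, left = (ch - h) // 2, (cw - w) // 2
    canvas[top:top + h, left:left + w] = image
    return canvas


def save_weights(net: Network, path) -> None:
    """Write network parameters to HDF5, one group per layer id."""
    with h5py.File(path, "w") as fh:
        fh.attrs["spec_name"] = net.spec.name
        fh.attrs["axes"] = "height,width,channels"
        for name, value, _ in net.parameters():
            layer, pname = name.split(".", 1)
            grp = fh.require_group(layer)
            grp.create_dataset(pname, data=value)


def load_weights(net: Network, path) -> Network:
    """Load parameters saved by :func:`save_weights` into ``net`` in place."""
    with h5py.File(path, "r") as fh:
        for name, value, _ in net.parameters():
            layer, pname = name.split(".", 1)
            value[...] = fh[layer][pname][...]
    return net


class SaliencyNetwork(BaseEstimator):
    """Scikit-learn style estimator wrapping the saliency network.

    Parameters
    ----------
    spec : str or NetworkSpec, default "tiny"
        Architecture to build — a bundled spec name ("tiny", "reference")
        or a :class:`NetworkSpec`.
    learning_rate, batch_size, epochs : training hyperparameters
        (full-scale defaults 5e-5 / 20 / 250).
    seed : int
        Controls both filter initialisation and batch shuffling.
    use_bias : bool
        Include a per-filter bias (initialised to zero).

    Attributes
    ----------
    net_ : Network
        The assembled, trained network.
    loss_history_ : list of float
        Mean Euclidean loss per epoch.
    checkpoints_ : dict epoch -> Network
        Deep snapshots taken at the requested checkpoint epochs.
    """

    def __init__(self, spec="tiny", learning_rate=5.0e-5, batch_size=20,
                 epochs=250, seed=0, use_bias=True, checkpoint_epochs=()):
        self.spec = spec
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.use_bias = use_bias
        self.checkpoint_epochs = checkpoint_epochs

    def _resolve_spec(self) -> NetworkSpec:
        if isinstance(self.spec, NetworkSpec):
            return self.spec
        return NetworkSpec.bundled(self.spec)

    def fit(self, X, y):
        """Train on images ``X (N, H, W, 3)`` and target maps ``y (N, H, W)``."""
        import copy

        spec = self._resolve_spec()
        self.net_ = build_network(spec, seed=self.seed, use_bias=self.use_bias)
        cfg = TrainingConfig(learning_rate=self.learning_rate,
                             batch_size=self.batch_size,
                             epochs=self.epochs, seed=self.seed)
        self.checkpoints_ = {}

        def snap(epoch, net):
            self.checkpoints_[epoch] = copy.deepcopy(net)

        pairs = list(zip(np.asarray(X, dtype=np.float64),
                         np.asarray(y, dtype=np.float64)))
        self.loss_history_ = train(self.net_, pairs, cfg,
                                   checkpoints=self.checkpoint_epochs,
                                   on_checkpoint=snap)
        return self

    def predict(self, X):
        """Saliency maps (N, H, W), clipped to [0, 1]."""
        X = np.asarray(X, dtype=np.float64)
        out = self.net_.forward(X)[..., 0]
        return np.clip(out, 0.0, 1.0)

    def record(self, stimulus, stimulus_id=None):
        """Per-layer activation tensors for one embedded stimulus."""
        return forward_record(self.net_, stimulus, stimulus_id=stimulus_id)
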