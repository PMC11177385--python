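"""Multi-site synthetic ROI time-series generator.

Emulates D acquisition sites, each contributing labelled T x N matrices
(time nodes x brain regions). The class signal is a rank-1 spatial pattern
constant over time: class-1 samples receive ``shared_effect`` along a
unit-norm region pattern drawn once per spec (identical across sites — the
"correlated tasks" premise) plus ``private_effect`` along a site-specific
pattern, on top of i.i.d. Gaussian noise. An optional low-frequency
temporal modulation can be applied to the signal. Generation is a pure
function of (spec, task_index): the same spec always yields bitwise
identical data.

``default_abide_spec`` mirrors the two-site ABIDE setting used as the
reference protocol: site sizes 172 (74 ill / 98 control) and 120 (47 / 73).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import RoiTimeSeries, TaskDataset


class SyntheticConfigError(ValueError):
    """Raised when a generator spec field is invalid; names the field."""


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic multi-site study.

    Attributes
    ----------
    n_tasks : int
        Number of sites D (each one classification task).
    class_counts : tuple of (n_ill, n_control) per task
        Per-site sample counts; a count may be 0 only deliberately.
    T, N : int
        Time nodes and brain regions per sample.
    shared_effect : float >= 0
        Amplitude of the class signal common to all sites.
    private_effect : float >= 0
        Amplitude of the class signal unique to each site.
    noise_sd : float > 0
        Standard deviation of the i.i.d. Gaussian noise per entry.
    seed : int
        Root seed; all randomness derives from it.
    temporal_modulation : bool
        If True, the class signal is modulated by 1 + 0.5 sin(2*pi*t/T).
    task_names : tuple of str
        Optional site names; defaults to "site0", "site1", ...
    """

    n_tasks: int
    class_counts: tuple[tuple[int, int], ...]
    T: int = 30
    N: int = 116
    shared_effect: float = 0.6
    private_effect: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0
    temporal_modulation: bool = False
    task_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_tasks < 1:
            raise SyntheticConfigError(f"n_tasks must be >= 1, got {self.n_tasks}")
        self.class_counts = tuple(tuple(int(c) for c in cc) for cc in self.class_counts)
        if len(self.class_counts) != self.n_tasks:
            raise SyntheticConfigError(
                f"class_counts must have one (n_ill, n_control) pair per task: "
                f"got {len(self.class_counts)} pairs for n_tasks={self.n_tasks}"
            )
        for d, (npos, nneg) in enumerate(self.class_counts):
            if npos < 0 or nneg < 0 or npos + nneg < 1:
                raise SyntheticConfigError(
                    f"class_counts[{d}] must be non-negative with >= 1 sample, "
                    f"got {(npos, nneg)}"
                )
        if self.T < 2:
            raise SyntheticConfigError(f"T must be >= 2, got {self.T}")
        if self.N < 2:
            raise SyntheticConfigError(f"N must be >= 2, got {self.N}")
        if self.shared_effect < 0:
            raise SyntheticConfigError(
                f"shared_effect must be >= 0, got {self.shared_effect}"
            )
        if self.private_effect < 0:
            raise SyntheticConfigError(
                f"private_effect must be >= 0, got {self.private_effect}"
            )
        if not self.noise_sd > 0:
            raise SyntheticConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.task_names and len(self.task_names) != self.n_tasks:
            raise SyntheticConfigError(
                f"task_names must be empty or length n_tasks, got {len(self.task_names)}"
            )

    def name_of(self, d: int) -> str:
        return self.task_names[d] if self.task_names else f"site{d}"


def shared_pattern(spec: SyntheticSpec) -> np.ndarray:
    """Unit-norm region pattern carrying the shared class signal."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    u = rng.standard_normal(spec.N)
    return u / np.linalg.norm(u)


def generate_task_data(spec: SyntheticSpec, task_index: int) -> TaskDataset:
    """Generate one site's labelled dataset.

    Class-1 samples carry the shared pattern scaled by ``shared_effect``
    plus a site-private unit-norm pattern scaled by ``private_effect``,
    added to every time row (optionally modulated); all samples carry
    Gaussian noise of sd ``noise_sd``.
    """
    if not 0 <= task_index < spec.n_tasks:
        raise SyntheticConfigError(
            f"task_index must be in [0, {spec.n_tasks}), got {task_index}"
        )
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_tasks + 1)
    u = shared_pattern(spec)
    rng = np.random.default_rng(children[1 + task_index])
    v = rng.standard_normal(spec.N)
    v /= np.linalg.norm(v)

    if spec.temporal_modulation:
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * np.arange(spec.T) / spec.T)
    else:
        mod = np.ones(spec.T)
    signal = mod[:, None] * (spec.shared_effect * u + spec.private_effect * v)[None, :]

    n_pos, n_neg = spec.class_counts[task_index]
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    samples = []
    for i, label in enumerate(labels):
        mat = spec.noise_sd * rng.standard_normal((spec.T, spec.N))
        if label == 1:
            mat = mat + signal
        samples.append(
            RoiTimeSeries(
                subject_id=f"{spec.name_of(task_index)}_s{i:04d}",
                task_index=task_index,
                matrix=mat,
                label=int(label),
            )
        )
    return TaskDataset(task_index=task_index, samples=samples, name=spec.name_of(task_index))


def generate_all(spec: SyntheticSpec) -> list[TaskDataset]:
    """All D site datasets for one spec."""
    return [generate_task_data(spec, d) for d in range(spec.n_tasks)]


def default_abide_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Two-site spec echoing the reference demographics.

    Site 0 ("NYU"): 74 ill / 98 control (172 total); site 1 ("UM"):
    47 ill / 73 control (120 total). T defaults to 176 time nodes (a
    typical scan length for the first site) and N to 116 regions (the AAL
    atlas convention); both are conventions, not facts of the protocol.
    """
    kwargs = dict(
        n_tasks=2,
        class_counts=((74, 98), (47, 73)),
        T=176,
        N=116,
        shared_effect=0.6,
        private_effect=0.3,
        noise_sd=1.0,
        seed=seed,
        task_names=("NYU", "UM"),
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)
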