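"""Processing engine: picture queue, directory walker, worker pool.

The pipeline mirrors online beamline operation: filenames of frames to reduce
are collected in a central, de-duplicating FIFO (the *picture queue*), filled
either by a recursive directory walker (offline / local-server mode) or by
"new file" events published by a feeder process (online mode, see
:mod:`azimint.network`).  A pool of worker threads drains the queue; each
worker takes one image after the other, integrates it, writes the ``.chi``
file (plus slice files when configured) and appends a classifier record to
the shared history.  A corrupt frame increments the failure counter and never
stops the pool, and output contents are independent of the worker count.
"""

from __future__ import annotations

import json
import logging
import threading
import time
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .calibration import CalibrationSpec
from .classifiers import ClassifierHistory, acquisition_time, compute_classifiers
from .geometry import build_qmap
from .integrator import build_binning, build_weight_matrix, integrate_frame, write_chi
from .masks import load_mask
from .slices import extract_slice, write_slice_chi

__all__ = [
    "FileEvent",
    "QueueStatus",
    "PictureQueue",
    "IntegrationEngine",
    "directory_walk",
    "run_workers",
    "run_local_server",
]

log = logging.getLogger("azimint")

IMAGE_EXTENSIONS = (".tif", ".tiff")
PROCESSED_SIDECAR = ".azimint_processed"


@dataclass(frozen=True)
class FileEvent:
    """A feeder announcement: the 'new file' command plus the image path."""

    argument: str
    command: str = "new file"

    def __post_init__(self) -> None:
        if self.command == "new file" and not self.argument:
            raise ValueError("a 'new file' event needs a non-empty argument")

    def to_json(self) -> str:
        return json.dumps({"command": self.command, "argument": self.argument})

    @classmethod
    def from_json(cls, text: str) -> "FileEvent":
        doc = json.loads(text)
        return cls(command=doc["command"], argument=doc["argument"])


@dataclass(frozen=True)
class QueueStatus:
    """Snapshot of queue progress for monitoring."""

    pending: int
    completed: int
    failed: int
    rate: float
    active: bool


class PictureQueue:
    """Thread-safe de-duplicating FIFO of image paths.

    Every distinct path is accepted at most once per queue lifetime, which is
    what makes the pipeline exactly-once regardless of how many feeders or
    walkers race to announce the same frame.  ``abort`` clears pending work
    and deactivates the queue; subsequent events are dropped with a warning.
    """

    def __init__(self, active: bool = True) -> None:
        self._lock = threading.Lock()
        self._items: deque[str] = deque()
        self._seen: set[str] = set()
        self._accepted = 0
        self._completed = 0
        self._failed = 0
        self._active = active
        self._done_times: deque[float] = deque(maxlen=256)

    def enqueue(self, item: "FileEvent | str") -> bool:
        path = item.argument if isinstance(item, FileEvent) else str(item)
        with self._lock:
            if not self._active:
                log.warning("queue inactive, dropping event for %s", path)
                return False
            if path in self._seen:
                return False
            self._seen.add(path)
            self._items.append(path)
            self._accepted += 1
            return True

    def try_get(self) -> str | None:
        with self._lock:
            if self._items:
                return self._items.popleft()
            return None

    def mark_completed(self, path: str) -> None:
        with self._lock:
            self._completed += 1
            self._done_times.append(time.monotonic())

    def mark_failed(self, path: str) -> None:
        with self._lock:
            self._failed += 1

    def abort(self) -> int:
        """Clear pending items and deactivate; returns the number dropped."""
        with self._lock:
            dropped = len(self._items)
            self._accepted -= dropped
            self._items.clear()
            self._active = False
            return dropped

    def activate(self) -> None:
        with self._lock:
            self._active = True

    def forget_seen(self) -> None:
        """Allow already-enqueued paths again (used by 'reintegrate')."""
        with self._lock:
            self._seen.clear()

    @property
    def empty(self) -> bool:
        with self._lock:
            return not self._items

    @property
    def drained(self) -> bool:
        """True when every accepted item has been completed or failed."""
        with self._lock:
            return not self._items and self._completed + self._failed >= self._accepted

    def status(self, window_s: float = 10.0) -> QueueStatus:
        with self._lock:
            now = time.monotonic()
            recent = sum(1 for t in self._done_times if now - t <= window_s)
            return QueueStatus(
                pending=len(self._items),
                completed=self._completed,
                failed=self._failed,
                rate=recent / window_s,
                active=self._active,
            )


def directory_walk(roots, known=frozenset()) -> list[str]:
    """Recursively list image files under ``roots`` not already in ``known``.

    Deterministic: results are sorted lexicographically.  Non-image files are
    excluded by extension.  A missing root raises ``FileNotFoundError``.
    """
    if isinstance(roots, (str, Path)):
        roots = [roots]
    found: list[str] = []
    for root in roots:
        root = Path(root)
        if not root.is_dir():
            raise FileNotFoundError(f"watch directory does not exist: {root}")
        for p in root.rglob("*"):
            if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS:
                sp = str(p)
                if sp not in known:
                    found.append(sp)
    return sorted(found)


class IntegrationEngine:
    """Calibration-derived state reused across frames.

    Loads the pixel masks, builds the q map, radial binning and sparse
    weighting matrix once per mask entry, and exposes :meth:`process` to
    reduce a single image file to its output products.  An empty
    ``path to file`` in a mask entry means "no pixels masked".
    """

    def __init__(self, calibration: CalibrationSpec, base_dir=None) -> None:
        self.calibration = calibration
        geom = calibration.geometry
        base = Path(base_dir) if base_dir else None
        self.masks = []
        self.binnings = []
        self.weights = []
        for mspec in calibration.masks:
            if mspec.path_to_file:
                mpath = Path(mspec.path_to_file)
                if base is not None and not mpath.is_absolute():
                    mpath = base / mpath
                mask = load_mask(mpath, geom.image_size)
            else:
                mask = np.zeros(geom.image_size, dtype=bool)
            qmap = build_qmap(geom, calibration.wavelength)
            binning = build_binning(qmap, mask, mspec.pix_per_rad_element, geom)
            W = build_weight_matrix(
                geom, calibration.wavelength, binning, mask, mspec.oversampling
            )
            self.masks.append(mask)
            self.binnings.append(binning)
            self.weights.append(W)

    def read_frame(self, path) -> np.ndarray:
        frame = tifffile.imread(path)
        if frame.ndim != 2:
            raise ValueError(f"{path}: expected a single-page 2D image")
        expected = tuple(self.calibration.geometry.image_size)
        if frame.shape != expected:
            raise ValueError(f"{path}: frame shape {frame.shape} != calibration {expected}")
        return frame

    def reduce(self, frame: np.ndarray):
        """Integrate a frame with every configured mask; returns the curves."""
        return [
            integrate_frame(frame, W, binning)
            for W, binning in zip(self.weights, self.binnings)
        ]

    def process(self, image_path, out_dir):
        """Reduce one image file: write .chi (and slice) files, return the
        classifier record computed from the first mask's curve."""
        image_path = Path(image_path)
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame = self.read_frame(image_path)
        curves = self.reduce(frame)
        stem = image_path.stem
        for i, curve in enumerate(curves):
            name = f"{stem}.chi" if i == 0 else f"{stem}_m{i}.chi"
            write_chi(curve, out_dir / name, header_lines=(f"source: {image_path.name}",))
        geom = self.calibration.geometry
        for j, sspec in enumerate(self.calibration.slices):
            mask = self.masks[sspec.mask_reference]
            sc = extract_slice(frame, sspec, mask, geom, self.calibration.wavelength)
            write_slice_chi(
                sc, out_dir / f"{stem}_slice{j}_{sspec.direction}{sspec.position}.chi"
            )
        mspec = self.calibration.masks[0]
        return compute_classifiers(
            curves[0], mspec, image_path.name, acquisition_time(image_path)
        )


def run_workers(
    queue: PictureQueue,
    engine: IntegrationEngine,
    out_dir,
    history: ClassifierHistory,
    n_workers: int = 1,
    on_done=None,
) -> None:
    """Drain the queue with ``n_workers`` threads.

    Failures are logged and counted without stopping the pool.  The history is
    time-sorted on insertion, so results are independent of worker scheduling.
    """
    hist_lock = threading.Lock()

    def work() -> None:
        while True:
            path = queue.try_get()
            if path is None:
                return
            try:
                record = engine.process(path, out_dir)
            except Exception as exc:  # noqa: BLE001 — fault isolation by design
                log.warning("failed to process %s: %s", path, exc)
                queue.mark_failed(path)
                continue
            with hist_lock:
                history.insert(record)
            queue.mark_completed(path)
            if on_done is not None:
                on_done(path)

    threads = [threading.Thread(target=work, daemon=True) for _ in range(max(1, n_workers))]
    for t in threads:
        t.start()
    for t in threads:
        t.join()


def _read_processed(out_dir: Path) -> set[str]:
    sidecar = out_dir / PROCESSED_SIDECAR
    if not sidecar.is_file():
        return set()
    return {line.strip() for line in sidecar.read_text().splitlines() if line.strip()}


def _append_processed(out_dir: Path, paths) -> None:
    with open(out_dir / PROCESSED_SIDECAR, "a", encoding="utf-8") as fh:
        for p in paths:
            fh.write(f"{p}\n")


def run_local_server(
    calibration: CalibrationSpec,
    working_directory=None,
    out_dir=None,
    history: ClassifierHistory | None = None,
    reintegrate: bool = False,
    base_dir=None,
) -> tuple[QueueStatus, ClassifierHistory]:
    """Offline mode: walk the working directory, drain the queue, return.

    ``working_directory`` overrides the calibration's ``directory`` list and
    acts as the root for both input frames and (by default) the output files.
    Paths recorded in the sidecar of completed work are skipped on re-runs
    unless ``reintegrate`` is set.
    """
    roots = [working_directory] if working_directory else list(calibration.directory)
    if not roots:
        raise ValueError("no directory to process: give working_directory or set 'directory'")
    for root in roots:
        if not Path(root).is_dir():
            raise FileNotFoundError(f"watch directory does not exist: {root}")
    out_dir = Path(out_dir) if out_dir else Path(roots[0])
    out_dir.mkdir(parents=True, exist_ok=True)
    known = set() if reintegrate else _read_processed(out_dir)
    engine = IntegrationEngine(calibration, base_dir=base_dir)
    queue = PictureQueue(active=True)
    history = history if history is not None else ClassifierHistory()
    for path in directory_walk(roots, known=known):
        queue.enqueue(path)
    done: list[str] = []
    done_lock = threading.Lock()

    def on_done(path: str) -> None:
        with done_lock:
            done.append(path)

    run_workers(queue, engine, out_dir, history, calibration.threads, on_done=on_done)
    _append_processed(out_dir, sorted(done))
    return queue.status(), history
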