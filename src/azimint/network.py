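"""Networked operation: feeder publisher, remote server, control interface.

Online mode couples three processes over plain, open protocols:

* the *feeder* runs next to the data store, watches for freshly written
  frames and publishes a ``{"command": "new file", "argument": <path>}`` JSON
  event to its subscribers — only once the file size is stable, so the server
  never touches a half-written image (default port 5555);
* the *remote server* subscribes to those events, keeps the picture queue and
  worker pool alive indefinitely, and accepts four control commands over a
  minimal HTTP interface: ``new`` (install a calibration, rebuilding the
  weighting matrix), ``reintegrate`` (re-walk the watched directories),
  ``abort`` (clear pending work) and ``status``;
* an optional shared secret turns on HMAC-SHA256 authentication of control
  requests (header ``X-Auth`` over the request body).

The pub/sub link is a TCP socket carrying newline-delimited JSON — the same
event contract as a message-queue PUB/SUB socket, kept dependency-free.
Addresses may be written ``tcp://host:port``.  The per-user network layout
(feeder/server addresses, secret) lives in ``~/.saxsdognetwork`` as
``key=value`` lines.
"""

from __future__ import annotations

import hashlib
import hmac
import json
import logging
import socket
import threading
import time
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

from .calibration import CalibrationSpec, parse_calibration
from .classifiers import ClassifierHistory
from .pipeline import FileEvent, IntegrationEngine, PictureQueue, directory_walk

__all__ = [
    "parse_endpoint",
    "read_network_config",
    "EventPublisher",
    "EventSubscriber",
    "Feeder",
    "feeder_publish",
    "RemoteServer",
    "send_command",
    "sign_body",
    "wait_for_stable_file",
]

log = logging.getLogger("azimint.network")

DEFAULT_PUB_PORT = 5555
NETWORK_CONFIG = Path.home() / ".saxsdognetwork"


def parse_endpoint(endpoint: str, default_port: int = DEFAULT_PUB_PORT) -> tuple[str, int]:
    """Parse ``tcp://host:port`` (or ``host:port``) into an address tuple.

    ``*`` as the host means all interfaces (bind side).
    """
    ep = endpoint
    if ep.startswith("tcp://"):
        ep = ep[len("tcp://") :]
    host, _, port = ep.rpartition(":")
    if not host:
        host, port = ep, str(default_port)
    if host == "*":
        host = ""
    return host, int(port)


def read_network_config(path=None) -> dict[str, str]:
    """Read the ``key=value`` network layout file; missing file → empty dict."""
    path = Path(path) if path else NETWORK_CONFIG
    conf: dict[str, str] = {}
    if not path.is_file():
        return conf
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        conf[key.strip()] = value.strip()
    return conf


def sign_body(secret: str, body: bytes) -> str:
    """HMAC-SHA256 hex digest of a control-request body."""
    return hmac.new(secret.encode(), body, hashlib.sha256).hexdigest()


class EventPublisher:
    """Feeder-side publish socket: subscribers connect, every published event
    is sent to all of them as one JSON line."""

    def __init__(self, endpoint: str = f"tcp://*:{DEFAULT_PUB_PORT}") -> None:
        host, port = parse_endpoint(endpoint)
        self._server = socket.create_server((host, port))
        self.port = self._server.getsockname()[1]
        self._clients: list[socket.socket] = []
        self._lock = threading.Lock()
        self._closing = threading.Event()
        self._acceptor = threading.Thread(target=self._accept_loop, daemon=True)
        self._acceptor.start()

    def _accept_loop(self) -> None:
        while not self._closing.is_set():
            try:
                conn, _ = self._server.accept()
            except OSError:
                return
            with self._lock:
                self._clients.append(conn)

    def publish(self, event: FileEvent) -> int:
        """Send one event to every connected subscriber; returns the count."""
        payload = (event.to_json() + "\n").encode()
        sent = 0
        with self._lock:
            alive = []
            for conn in self._clients:
                try:
                    conn.sendall(payload)
                    alive.append(conn)
                    sent += 1
                except OSError:
                    conn.close()
            self._clients = alive
        return sent

    @property
    def n_subscribers(self) -> int:
        with self._lock:
            return len(self._clients)

    def close(self) -> None:
        self._closing.set()
        self._server.close()
        with self._lock:
            for conn in self._clients:
                conn.close()
            self._clients.clear()


class EventSubscriber:
    """Server-side subscription: connects to a publisher and hands each
    decoded :class:`FileEvent` to a callback on a background thread."""

    def __init__(self, endpoint: str, callback, connect_timeout: float = 5.0) -> None:
        host, port = parse_endpoint(endpoint)
        self._sock = socket.create_connection((host or "127.0.0.1", port), timeout=connect_timeout)
        self._sock.settimeout(0.2)
        self._callback = callback
        self._closing = threading.Event()
        self._thread = threading.Thread(target=self._recv_loop, daemon=True)
        self._thread.start()

    def _recv_loop(self) -> None:
        buf = b""
        while not self._closing.is_set():
            try:
                chunk = self._sock.recv(4096)
            except socket.timeout:
                continue
            except OSError:
                return
            if not chunk:
                return
            buf += chunk
            while b"\n" in buf:
                line, buf = buf.split(b"\n", 1)
                if not line.strip():
                    continue
                try:
                    event = FileEvent.from_json(line.decode())
                except (ValueError, KeyError) as exc:
                    log.warning("malformed event skipped: %s", exc)
                    continue
                self._callback(event)

    def close(self) -> None:
        self._closing.set()
        try:
            self._sock.shutdown(socket.SHUT_RDWR)
        except OSError:
            pass
        self._sock.close()
        self._thread.join(timeout=2.0)


def wait_for_stable_file(path, interval_s: float = 0.1, attempts: int = 50) -> bool:
    """True once the file exists and its size is unchanged across two polls.

    This is the feeder's completeness rule: an event may only be sent for a
    fully written image.
    """
    path = Path(path)
    last = -1
    for _ in range(attempts):
        if path.is_file():
            size = path.stat().st_size
            if size == last and size > 0:
                return True
            last = size
        time.sleep(interval_s)
    return False


def feeder_publish(publisher: EventPublisher, image_path, interval_s: float = 0.1) -> bool:
    """Publish a 'new file' event once the image is fully written."""
    if not wait_for_stable_file(image_path, interval_s=interval_s):
        log.warning("file never stabilized, not publishing: %s", image_path)
        return False
    publisher.publish(FileEvent(argument=str(image_path)))
    return True


class Feeder:
    """Polling watcher that announces new images in a directory tree."""

    def __init__(self, root, endpoint: str = f"tcp://*:{DEFAULT_PUB_PORT}", poll_s: float = 0.2):
        self.root = Path(root)
        self.publisher = EventPublisher(endpoint)
        self.poll_s = poll_s
        self._known: set[str] = set()
        self._stop = threading.Event()

    def scan_once(self) -> list[str]:
        """Announce every new stable image; returns the published paths."""
        published = []
        for path in directory_walk([self.root], known=self._known):
            if feeder_publish(self.publisher, path, interval_s=self.poll_s / 2):
                self._known.add(path)
                published.append(path)
        return published

    def run(self) -> None:
        while not self._stop.is_set():
            self.scan_once()
            self._stop.wait(self.poll_s)

    def stop(self) -> None:
        self._stop.set()
        self.publisher.close()


class RemoteServer:
    """Long-running reduction service fed by events, steered over HTTP.

    The worker pool runs for the lifetime of the server; 'new' swaps in a
    freshly built engine (weighting matrix and all) without restarting it.
    """

    def __init__(
        self,
        calibration: CalibrationSpec,
        out_dir,
        subscribe: str | None = None,
        control_port: int = 0,
        secret: str | None = None,
        base_dir=None,
    ) -> None:
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.secret = secret
        self.history = ClassifierHistory()
        self.queue = PictureQueue(active=True)
        self._base_dir = base_dir
        self._engine_lock = threading.Lock()
        self._engine = IntegrationEngine(calibration, base_dir=base_dir)
        self._calibration = calibration
        self._stop = threading.Event()
        self._hist_lock = threading.Lock()
        self._subscriber = (
            EventSubscriber(subscribe, self.queue.enqueue) if subscribe else None
        )
        self._workers = [
            threading.Thread(target=self._work_loop, daemon=True)
            for _ in range(max(1, calibration.threads))
        ]
        for t in self._workers:
            t.start()
        self._http = _make_control_server(self, control_port)
        self.control_port = self._http.server_address[1]
        self._http_thread = threading.Thread(target=self._http.serve_forever, daemon=True)
        self._http_thread.start()

    # -- worker pool ---------------------------------------------------
    def _work_loop(self) -> None:
        while not self._stop.is_set():
            path = self.queue.try_get()
            if path is None:
                time.sleep(0.02)
                continue
            with self._engine_lock:
                engine = self._engine
            try:
                record = engine.process(path, self.out_dir)
            except Exception as exc:  # noqa: BLE001 — fault isolation by design
                log.warning("failed to process %s: %s", path, exc)
                self.queue.mark_failed(path)
                continue
            with self._hist_lock:
                self.history.insert(record)
            self.queue.mark_completed(path)

    # -- control commands ---------------------------------------------
    def handle_command(self, doc: dict) -> dict:
        command = doc.get("command")
        if command == "status":
            st = self.queue.status()
            return {
                "ok": True,
                "pending": st.pending,
                "completed": st.completed,
                "failed": st.failed,
                "rate": st.rate,
                "active": st.active,
            }
        if command == "abort":
            dropped = self.queue.abort()
            return {"ok": True, "dropped": dropped}
        if command == "new":
            cal_doc = doc.get("calibration")
            if cal_doc is None:
                return {"ok": False, "error": "'new' needs a calibration"}
            try:
                calibration = parse_calibration(cal_doc)
                engine = IntegrationEngine(calibration, base_dir=self._base_dir)
            except Exception as exc:  # noqa: BLE001 — report, keep old state
                return {"ok": False, "error": str(exc)}
            with self._engine_lock:
                self._engine = engine
                self._calibration = calibration
            self.queue.activate()
            return {"ok": True}
        if command == "reintegrate":
            self.queue.activate()
            self.queue.forget_seen()
            with self._engine_lock:
                roots = list(self._calibration.directory)
            n = 0
            for root in roots:
                if Path(root).is_dir():
                    for path in directory_walk([root]):
                        if self.queue.enqueue(path):
                            n += 1
            return {"ok": True, "enqueued": n}
        return {"ok": False, "error": f"unknown command {command!r}"}

    def drain(self, timeout_s: float = 60.0) -> bool:
        """Block until the queue is empty and workers are idle (for tests)."""
        deadline = time.monotonic() + timeout_s
        while time.monotonic() < deadline:
            if self.queue.drained:
                return True
            time.sleep(0.05)
        return False

    def stop(self) -> None:
        self._stop.set()
        if self._subscriber is not None:
            self._subscriber.close()
        self._http.shutdown()
        self._http.server_close()
        for t in self._workers:
            t.join(timeout=2.0)


def _make_control_server(server: RemoteServer, port: int) -> ThreadingHTTPServer:
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, fmt, *args):  # quiet
            log.debug(fmt, *args)

        def _reply(self, code: int, doc: dict) -> None:
            body = json.dumps(doc).encode()
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_POST(self) -> None:
            length = int(self.headers.get("Content-Length", "0"))
            body = self.rfile.read(length)
            if server.secret:
                provided = self.headers.get("X-Auth", "")
                if not hmac.compare_digest(provided, sign_body(server.secret, body)):
                    self._reply(401, {"ok": False, "error": "authentication failed"})
                    return
            try:
                doc = json.loads(body.decode() or "{}")
            except json.JSONDecodeError:
                self._reply(400, {"ok": False, "error": "body must be JSON"})
                return
            result = server.handle_command(doc)
            self._reply(200 if result.get("ok") else 400, result)

        def do_GET(self) -> None:
            if self.path.rstrip("/") in ("", "/status"):
                self._reply(200, server.handle_command({"command": "status"}))
            else:
                self._reply(404, {"ok": False, "error": "unknown route"})

    return ThreadingHTTPServer(("127.0.0.1", port), Handler)


def send_command(control_port: int, doc: dict, secret: str | None = None, host="127.0.0.1") -> dict:
    """Send one control command to a running server; returns the reply."""
    import urllib.error
    import urllib.request

    body = json.dumps(doc).encode()
    req = urllib.request.Request(
        f"http://{host}:{control_port}/", data=body, headers={"Content-Type": "application/json"}
    )
    if secret:
        req.add_header("X-Auth", sign_body(secret, body))
    try:
        with urllib.request.urlopen(req, timeout=10) as resp:
            return json.loads(resp.read().decode())
    except urllib.error.HTTPError as exc:
        return json.loads(exc.read().decode())
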