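"""Mock IoT gateway: identity lookup, confirmation and measurement upload.

The physical device talks to a cloud database over cellular HTTP using two
GET endpoints — one returning the participant name for an ID (so the
operator can confirm identity) and one inserting a measured BrAC for that
ID.  This module reproduces the protocol against a pluggable transport so
the whole device flow is testable without hardware:

* :class:`TelemetryStore` is the database stand-in (participants and
  measurements tables, JSON file persistence);
* :class:`InProcessTransport` dispatches GET-style query strings
  (``get_name?id=...``, ``insert?id=...&brac=...``) directly to a store;
* :func:`serve` exposes the same dispatcher over local HTTP
  (stdlib ``http.server``) and :class:`HttpTransport` talks to it, for an
  end-to-end stateless-protocol check;
* :func:`run_session` is the device-side state machine: read ID, look up
  the name, confirm, quantify a breath trace and upload.

Requests are independent of each other (HTTP statelessness): no session
state lives in the transport, so a server restart between the lookup and
the upload does not change the outcome.
"""

from __future__ import annotations

import json
import threading
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from urllib.parse import parse_qs, quote, urlsplit
from urllib.request import urlopen

from .model import BreathAlcoholResults, ThresholdParams
from .simulate import SensorTrace

__all__ = [
    "NotFoundError",
    "UploadRejectedError",
    "ParticipantRecord",
    "MeasurementRecord",
    "TelemetryStore",
    "InProcessTransport",
    "HttpTransport",
    "GatewayClient",
    "SessionStatus",
    "SessionOutcome",
    "run_session",
    "serve",
]


class NotFoundError(KeyError):
    """Unknown participant ID."""


class UploadRejectedError(ValueError):
    """Malformed or invalid measurement."""


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    name: str

    def __post_init__(self):
        if not self.participant_id or not self.participant_id.isdigit():
            raise ValueError("participant_id must be a non-empty digit string")


@dataclass(frozen=True)
class MeasurementRecord:
    participant_id: str
    brac: float
    timestamp: str = ""

    def __post_init__(self):
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        if self.brac < 0:
            raise ValueError("BrAC must be non-negative")


class TelemetryStore:
    """In-memory database stand-in with two tables and JSON persistence."""

    def __init__(self):
        self._participants: dict[str, ParticipantRecord] = {}
        self._measurements: list[MeasurementRecord] = []

    def add_participant(self, participant_id: str, name: str) -> None:
        rec = ParticipantRecord(participant_id, name)
        if rec.participant_id in self._participants:
            raise ValueError(f"participant {participant_id} already exists")
        self._participants[rec.participant_id] = rec

    def get_name(self, participant_id: str) -> str:
        try:
            return self._participants[participant_id].name
        except KeyError:
            raise NotFoundError(participant_id) from None

    def add_measurement(
        self, participant_id: str, brac: float, timestamp: str | None = None
    ) -> MeasurementRecord:
        if participant_id not in self._participants:
            raise NotFoundError(participant_id)
        if timestamp is None:
            # timestamps originate at the store on insert
            timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        rec = MeasurementRecord(participant_id, float(brac), timestamp)
        self._measurements.append(rec)
        return rec

    def measurements_for(self, participant_id: str) -> list[MeasurementRecord]:
        return [m for m in self._measurements if m.participant_id == participant_id]

    @property
    def n_measurements(self) -> int:
        return len(self._measurements)

    def save(self, path: str | Path) -> None:
        payload = {
            "participants": [
                {"participant_id": p.participant_id, "name": p.name}
                for p in self._participants.values()
            ],
            "measurements": [
                {
                    "participant_id": m.participant_id,
                    "brac": m.brac,
                    "timestamp": m.timestamp,
                }
                for m in self._measurements
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TelemetryStore":
        payload = json.loads(Path(path).read_text())
        store = cls()
        for p in payload.get("participants", []):
            store.add_participant(p["participant_id"], p["name"])
        for m in payload.get("measurements", []):
            store.add_measurement(m["participant_id"], m["brac"], m["timestamp"])
        return store


def _dispatch(store: TelemetryStore, path_query: str) -> tuple[int, str]:
    """Handle one GET-style request against the store.

    Returns (status, body) with plain-text bodies, mirroring the two
    server-side scripts of the real deployment.
    """
    parts = urlsplit(path_query)
    endpoint = parts.path.strip("/")
    params = {k: v[0] for k, v in parse_qs(parts.query).items()}
    if endpoint == "get_name":
        pid = params.get("id", "")
        if not pid:
            return 400, "missing id"
        try:
            return 200, store.get_name(pid)
        except NotFoundError:
            return 404, "not found"
    if endpoint == "insert":
        pid = params.get("id", "")
        if not pid:
            return 400, "missing id"
        try:
            brac = float(params["brac"])
        except (KeyError, ValueError):
            return 400, "malformed brac"
        if brac < 0:
            return 400, "malformed brac"
        try:
            rec = store.add_measurement(pid, brac)
        except NotFoundError:
            return 404, "not found"
        return 200, f"ok {rec.timestamp}"
    return 404, "unknown endpoint"


class InProcessTransport:
    """Request/response interface dispatching directly to a store."""

    def __init__(self, store: TelemetryStore):
        self.store = store

    def request(self, path_query: str) -> tuple[int, str]:
        return _dispatch(self.store, path_query)


class HttpTransport:
    """Transport over a local HTTP server started with :func:`serve`."""

    def __init__(self, base_url: str):
        self.base_url = base_url.rstrip("/")

    def request(self, path_query: str) -> tuple[int, str]:
        url = f"{self.base_url}/{path_query.lstrip('/')}"
        try:
            with urlopen(url) as resp:
                return resp.status, resp.read().decode()
        except Exception as exc:  # urllib raises on 4xx
            code = getattr(exc, "code", None)
            if code is not None:
                return int(code), exc.read().decode()  # type: ignore[attr-defined]
            raise


class GatewayClient:
    """Device-side client issuing the two GET requests through a transport."""

    def __init__(self, transport):
        self.transport = transport

    def lookup_participant(self, participant_id: str) -> str:
        if not participant_id:
            raise ValueError("participant id must be non-empty")
        status, body = self.transport.request(
            f"get_name?id={quote(participant_id)}"
        )
        if status == 404:
            raise NotFoundError(participant_id)
        if status != 200:
            raise UploadRejectedError(body)
        return body

    def upload_measurement(self, participant_id: str, brac: float) -> str:
        if not participant_id:
            raise ValueError("participant id must be non-empty")
        status, body = self.transport.request(
            f"insert?id={quote(participant_id)}&brac={quote(repr(float(brac)))}"
        )
        if status == 404:
            raise NotFoundError(participant_id)
        if status != 200:
            raise UploadRejectedError(body)
        return body


class SessionStatus(Enum):
    UPLOADED = "uploaded"
    ABORTED = "aborted"
    NOT_FOUND = "not-found"
    ERROR = "error"


@dataclass
class SessionOutcome:
    status: SessionStatus
    participant_name: str | None = None
    brac: float | None = None
    detail: str = ""


def run_session(
    transport,
    id_input: str,
    confirm: bool,
    trace: SensorTrace | None,
    results: BreathAlcoholResults,
    thresholds: ThresholdParams | None = None,
) -> SessionOutcome:
    """Run one device session: ID -> lookup -> confirm -> quantify -> upload.

    No upload ever happens without a successful lookup and an explicit
    confirmation in the same session.  Transport failures abort the
    session with a retryable ``ERROR`` outcome and persist nothing.
    """
    client = GatewayClient(transport)
    try:
        name = client.lookup_participant(id_input)
    except NotFoundError:
        return SessionOutcome(SessionStatus.NOT_FOUND, detail=id_input)
    except (ValueError, OSError) as exc:
        return SessionOutcome(SessionStatus.ERROR, detail=str(exc))
    if not confirm:
        return SessionOutcome(SessionStatus.ABORTED, participant_name=name)
    reading = results.quantify(trace, thresholds)
    try:
        ack = client.upload_measurement(id_input, reading.value)
    except (UploadRejectedError, NotFoundError, OSError) as exc:
        return SessionOutcome(
            SessionStatus.ERROR, participant_name=name, detail=str(exc)
        )
    return SessionOutcome(
        SessionStatus.UPLOADED,
        participant_name=name,
        brac=reading.value,
        detail=ack,
    )


class _Handler(BaseHTTPRequestHandler):
    store: TelemetryStore  # set on the subclass by serve()

    def do_GET(self):  # noqa: N802 (http.server API)
        status, body = _dispatch(self.store, self.path)
        payload = body.encode()
        self.send_response(status)
        self.send_header("Content-Type", "text/plain; charset=utf-8")
        self.send_header("Content-Length", str(len(payload)))
        self.end_headers()
        self.wfile.write(payload)

    def log_message(self, *args):  # quiet by default
        pass


def serve(
    store: TelemetryStore, host: str = "127.0.0.1", port: int = 0, background: bool = False
):
    """Serve the mock gateway over HTTP.

    With ``background=True`` the server runs in a daemon thread and the
    ``ThreadingHTTPServer`` instance is returned (its ``server_address``
    carries the bound port); call ``shutdown()`` to stop it.
    """
    handler = type("BoundHandler", (_Handler,), {"store": store})
    server = ThreadingHTTPServer((host, port), handler)
    if background:
        thread = threading.Thread(target=server.serve_forever, daemon=True)
        thread.start()
        return server
    try:
        server.serve_forever()
    finally:
        server.server_close()
    return server
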