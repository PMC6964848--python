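"""Local resumable task queue with a worker pool, plus CSV/JSON reporting.

Each :class:`Task` owns a deterministic id (a stable hash of its payload),
which makes runs idempotent: re-running with the same checkpoint skips
already-completed tasks, and output rows are sorted by task id so two runs
with identical inputs produce byte-identical CSVs regardless of worker
count or completion order.
"""

from __future__ import annotations

import csv
import hashlib
import json
import pickle
import time
from concurrent.futures import ProcessPoolExecutor, as_completed
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = ["Task", "RunReport", "make_task", "run_tasks", "pool_runner"]


def _stable_hash(payload) -> str:
    """Deterministic id for a payload; falls back to pickle for non-JSON types."""
    try:
        blob = json.dumps(payload, sort_keys=True, default=_json_default).encode()
    except TypeError:
        blob = pickle.dumps(payload)
    return hashlib.sha1(blob).hexdigest()[:16]


def _json_default(obj):
    # dataclasses and similar structured payloads hash via repr; adequate for
    # identity as long as reprs are deterministic (ours are)
    return repr(obj)


@dataclass(frozen=True)
class Task:
    task_id: str
    payload: dict


def make_task(payload: dict) -> Task:
    return Task(task_id=_stable_hash(payload), payload=payload)


@dataclass
class RunReport:
    total: int
    done: int
    failed: int
    skipped: int
    wall_time_s: float
    output_csv: Optional[str] = None
    checkpoint: Optional[str] = None

    @property
    def pending(self) -> int:
        return self.total - self.done - self.failed

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _execute(work_fn: Callable[[dict], dict], task: Task) -> Dict:
    try:
        row = work_fn(task.payload)
        return {"task_id": task.task_id, "status": "done", "row": row, "error": ""}
    except Exception as exc:
        return {"task_id": task.task_id, "status": "failed", "row": None,
                "error": f"{type(exc).__name__}: {exc}"}


def _read_checkpoint(path: Optional[Path]) -> Dict[str, dict]:
    """Checkpoint file: one JSON record per line, keyed by task_id."""
    done: Dict[str, dict] = {}
    if path and path.exists():
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rec = json.loads(line)
                    done[rec["task_id"]] = rec
    return done


def _run_records(
    tasks: Sequence[Task],
    work_fn: Callable[[dict], dict],
    workers: int,
    ckpt: Optional[Path],
) -> Tuple[Dict[str, dict], int]:
    """Execute tasks not present in the checkpoint; return all records."""
    previous = _read_checkpoint(ckpt)
    todo = [t for t in tasks if t.task_id not in previous]
    skipped = len(tasks) - len(todo)
    records: Dict[str, dict] = dict(previous)

    ckpt_fh = open(ckpt, "a") if ckpt else None

    def note(rec: dict) -> None:
        records[rec["task_id"]] = rec
        if ckpt_fh:
            ckpt_fh.write(json.dumps(rec, sort_keys=True) + "\n")
            ckpt_fh.flush()

    try:
        if workers == 1 or len(todo) <= 1:
            for t in todo:
                note(_execute(work_fn, t))
        else:
            with ProcessPoolExecutor(max_workers=workers) as pool:
                futures = [pool.submit(_execute, work_fn, t) for t in todo]
                for fut in as_completed(futures):
                    note(fut.result())
    finally:
        if ckpt_fh:
            ckpt_fh.close()
    return records, skipped


def run_tasks(
    tasks: Sequence[Task],
    work_fn: Callable[[dict], dict],
    workers: int = 1,
    checkpoint_path: Optional[str | Path] = None,
    output_csv: Optional[str | Path] = None,
    fieldnames: Optional[Sequence[str]] = None,
) -> RunReport:
    """Execute ``tasks`` with ``work_fn`` on a pool of ``workers`` processes.

    Completed task records are appended to the checkpoint as they finish; a
    restart with the same checkpoint executes only the remaining tasks.  A
    failing task is recorded as failed and the run continues (partial
    success still returns normally).  When ``output_csv`` is given, all
    result rows — including ones restored from the checkpoint — are written
    sorted by task id.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    t0 = time.monotonic()
    ckpt = Path(checkpoint_path) if checkpoint_path else None
    records, skipped = _run_records(tasks, work_fn, workers, ckpt)

    wanted = [t.task_id for t in tasks]
    done = sum(1 for i in wanted if records.get(i, {}).get("status") == "done")
    failed = sum(1 for i in wanted if records.get(i, {}).get("status") == "failed")
    if output_csv:
        _write_rows_csv(Path(output_csv), wanted, records, fieldnames)
    return RunReport(
        total=len(tasks),
        done=done,
        failed=failed,
        skipped=skipped,
        wall_time_s=time.monotonic() - t0,
        output_csv=str(output_csv) if output_csv else None,
        checkpoint=str(ckpt) if ckpt else None,
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def _write_rows_csv(
    path: Path,
    task_ids: Sequence[str],
    records: Dict[str, dict],
    fieldnames: Optional[Sequence[str]],
) -> None:
    rows = []
    for tid in sorted(task_ids):
        rec = records.get(tid)
        if rec is None:
            continue
        row = dict(rec["row"] or {})
        row["task_id"] = tid
        if rec["status"] == "failed":
            row["status"] = f"failed: {rec['error']}"
        else:
            row.setdefault("status", rec["status"])
        rows.append(row)
    if fieldnames is None:
        fieldnames = ["task_id"]
        for row in rows:
            for k in row:
                if k not in fieldnames:
                    fieldnames.append(k)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(fieldnames), restval="")
        w.writeheader()
        for row in rows:
            w.writerow({k: _fmt(row.get(k)) for k in fieldnames})


def pool_runner(workers: int, checkpoint_path: Optional[str | Path] = None):
    """Adapter for analyses-style scans: ``runner(work_fn, payloads) -> rows``.

    Executes payloads on ``workers`` processes via :func:`run_tasks`
    semantics and returns result rows in payload order.  Failed payloads
    yield a row with a ``failed: ...`` status and null values.
    """

    def runner(work_fn: Callable[[dict], dict], payloads: Iterable[dict]) -> List[dict]:
        tasks = [make_task(p) for p in payloads]
        ckpt = Path(checkpoint_path) if checkpoint_path else None
        records, _ = _run_records(tasks, work_fn, workers, ckpt)
        rows = []
        for t in tasks:
            rec = records[t.task_id]
            if rec["status"] == "done":
                rows.append(rec["row"])
            else:
                rows.append(
                    {"ko1": t.payload.get("ko1") or "",
                     "ko2": t.payload.get("ko2") or "",
                     "yield_min_rel_pct": None, "yield_max_rel_pct": None,
                     "status": f"failed: {rec['error']}"}
                )
        return rows

    return runner
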