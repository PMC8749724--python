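"""Monitoring state machine, survey triage, risk coding, and alerts.

Frames arrive at a fixed cadence with per-frame amplitude summaries
(g_body, g_bed, ir). A frame is *clear* when the abdomen accelerometer
dominates the bed accelerometer, and a *breath* when, in addition, the
body amplitude reaches the detection threshold g_th. A timer T counts
seconds since the last confirmed breath:

* T in [10, 20) s — limit risk condition: one apnea alert per pause, and
  a caregiver survey (SAT / BPM) is requested;
* T >= 20 s, or a continuously unclear signal for more than 20 s — the
  rescue process activates (actuator enable, red alert).

Unclear frames never reset T. After rescue only an explicit reset
resumes monitoring. Alerts are triaged by the survey (both SAT and BPM
strictly below 90 is critical), classified by a risk color (red =
immediate intervention, yellow = planned check-up, green = prospective
study record) and rendered as an eight-question (8Ws) structured record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Iterable, Optional

__all__ = [
    "MonitorConfig",
    "MonitorState",
    "Frame",
    "SurveyResponse",
    "AlertRecord",
    "monitor_step",
    "submit_survey",
    "reset_monitor",
    "evaluate_survey",
    "classify_risk",
    "render_alert",
    "run_monitor",
    "EIGHT_WS_KEYS",
    "RISK_LEGEND",
]

EIGHT_WS_KEYS = (
    "what", "where", "why", "who", "what_to_do", "which_tools", "when", "how",
)
RISK_LEGEND = {
    "red": "immediate intervention",
    "yellow": "planned check-up",
    "green": "prospective study",
}

MONITORING = "monitoring"
APNEA_ALERT = "apnea_alert"
AWAITING_SURVEY = "awaiting_survey"
RESCUE = "rescue"

TRIGGER_APNEA_ALERT = "apnea_10_20"
TRIGGER_APNEA_RESCUE = "apnea_over_20"
TRIGGER_UNCLEAR_RESCUE = "unclear_over_20"


@dataclass(frozen=True)
class MonitorConfig:
    g_th: float = 0.004          # g; amplitude of the minimum breathing displacement
    t_risk_s: float = 10.0
    t_apnea_s: float = 20.0
    frame_s: float = 0.25
    sat_threshold: float = 90.0
    bpm_threshold: float = 90.0
    location: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.t_risk_s < self.t_apnea_s:
            raise ValueError("need 0 < t_risk_s < t_apnea_s")
        if self.g_th <= 0 or self.frame_s <= 0:
            raise ValueError("g_th and frame_s must be positive")


@dataclass(frozen=True)
class Frame:
    """Per-frame summary: detrended peak-to-peak amplitudes in g and the
    IR displacement estimate (um)."""

    t_s: float
    g_body: float
    g_bed: float
    ir_um: float = 0.0


@dataclass(frozen=True)
class MonitorState:
    phase: str = MONITORING
    timer_T_s: float = 0.0
    unclear_elapsed_s: float = 0.0
    alert_fired: bool = False

    def __post_init__(self) -> None:
        if self.timer_T_s < 0 or self.unclear_elapsed_s < 0:
            raise ValueError("timers must be non-negative")


@dataclass(frozen=True)
class SurveyResponse:
    sat_pct: Optional[float] = None
    bpm: Optional[float] = None
    body_position: str = ""
    skin_color: str = ""
    free_notes: str = ""

    def __post_init__(self) -> None:
        if self.sat_pct is not None and not 0 <= self.sat_pct <= 100:
            raise ValueError("sat_pct must be in [0, 100]")
        if self.bpm is not None and self.bpm < 0:
            raise ValueError("bpm must be non-negative")


@dataclass
class AlertRecord:
    timestamp: float
    trigger: Optional[str]
    survey: Optional[SurveyResponse] = None
    survey_outcome: Optional[str] = None  # "critical" | "ok"
    risk_color: Optional[str] = None
    eight_ws: dict[str, str] = field(default_factory=dict)
    environment: dict = field(
        default_factory=lambda: {"temperature_c": None, "humidity_pct": None}
    )

    def __post_init__(self) -> None:
        full = {k: "" for k in EIGHT_WS_KEYS}
        full.update(self.eight_ws)
        self.eight_ws = full


def _event(kind: str, t: float, state: MonitorState, **extra) -> dict:
    ev = {"event": kind, "t_s": t, "phase": state.phase,
          "timer_T_s": round(state.timer_T_s, 6)}
    ev.update(extra)
    return ev


def monitor_step(
    frame: Frame, state: MonitorState, config: MonitorConfig
) -> tuple[MonitorState, list[dict]]:
    """Advance the machine by one frame; returns (new state, events).

    Malformed frames (negative metrics) are skipped with a warning event.
    The rescue phase is absorbing until :func:`reset_monitor`.
    """
    events: list[dict] = []
    if frame.g_body < 0 or frame.g_bed < 0:
        events.append(_event("warning", frame.t_s, state,
                             message="malformed frame skipped"))
        return state, events
    if state.phase == RESCUE:
        return state, events

    clear = frame.g_body > frame.g_bed
    breath = clear and frame.g_body >= config.g_th

    unclear_elapsed = 0.0 if clear else state.unclear_elapsed_s + config.frame_s
    if breath:
        # a confirmed breath ends the pause and resumes plain monitoring
        timer = 0.0
        phase = MONITORING
        alert_fired = False
    else:
        timer = state.timer_T_s + config.frame_s
        phase = state.phase
        alert_fired = state.alert_fired

    new = MonitorState(phase, timer, unclear_elapsed, alert_fired)

    if timer >= config.t_apnea_s or unclear_elapsed > config.t_apnea_s:
        # the trigger reports what the signal looked like when rescue fired:
        # a confirmed motionless pause vs an unreadable signal
        trigger = TRIGGER_APNEA_RESCUE if clear else TRIGGER_UNCLEAR_RESCUE
        new = replace(new, phase=RESCUE)
        events.append(_event("rescue", frame.t_s, new, trigger=trigger))
        events.append(_event("actuator_enable", frame.t_s, new))
    elif timer >= config.t_risk_s and not new.alert_fired:
        new = replace(new, phase=AWAITING_SURVEY, alert_fired=True)
        events.append(_event("apnea_alert", frame.t_s, new,
                             trigger=TRIGGER_APNEA_ALERT))
        events.append(_event("survey_request", frame.t_s, new))
    return new, events


def evaluate_survey(survey: SurveyResponse, config: MonitorConfig) -> str:
    """'critical' when both SAT and BPM are strictly below threshold (90);
    missing vitals are not evaluable and escalate (fail-safe)."""
    if survey.sat_pct is None or survey.bpm is None:
        return "critical"
    if survey.sat_pct < config.sat_threshold and survey.bpm < config.bpm_threshold:
        return "critical"
    return "ok"


def submit_survey(
    survey: SurveyResponse,
    state: MonitorState,
    config: MonitorConfig,
    t_s: float,
) -> tuple[MonitorState, list[dict]]:
    """Resolve a pending survey: critical activates rescue, ok resumes
    monitoring with the timer reset."""
    outcome = evaluate_survey(survey, config)
    if outcome == "critical":
        new = MonitorState(RESCUE, state.timer_T_s, state.unclear_elapsed_s, True)
        events = [_event("rescue", t_s, new, trigger=TRIGGER_APNEA_ALERT,
                         survey_outcome="critical")]
        events.append(_event("actuator_enable", t_s, new))
        return new, events
    new = MonitorState(MONITORING, 0.0, state.unclear_elapsed_s, False)
    return new, [_event("survey_ok", t_s, new, survey_outcome="ok")]


def reset_monitor(state: MonitorState, t_s: float) -> tuple[MonitorState, list[dict]]:
    """Explicit operator reset; the only exit from the rescue phase."""
    new = MonitorState()
    return new, [_event("reset", t_s, new)]


def classify_risk(record: AlertRecord) -> str:
    """Map a record to the risk color code."""
    if record.trigger in (TRIGGER_APNEA_RESCUE, TRIGGER_UNCLEAR_RESCUE):
        return "red"
    if record.survey_outcome == "critical":
        return "red"
    if record.trigger == TRIGGER_APNEA_ALERT:
        return "yellow"
    return "green"


def make_alert_record(
    timestamp: float,
    trigger: Optional[str],
    survey: Optional[SurveyResponse] = None,
    config: MonitorConfig | None = None,
) -> AlertRecord:
    """Build a record with the computable 8Ws fields auto-filled; the
    remaining questions are left for the operator."""
    config = config or MonitorConfig()
    record = AlertRecord(timestamp=timestamp, trigger=trigger, survey=survey)
    if survey is not None:
        record.survey_outcome = evaluate_survey(survey, config)
    record.risk_color = classify_risk(record)
    record.eight_ws.update(
        {
            "what": record.risk_color if trigger is None else trigger,
            "where": config.location,
            "when": f"t={timestamp:.2f}s",
            "what_to_do": RISK_LEGEND[record.risk_color],
        }
    )
    return record


def render_alert(record: AlertRecord) -> str:
    """Deterministic one-line alert message plus the full JSON record."""
    if record.risk_color is None:
        record.risk_color = classify_risk(record)
    parts = [
        f"[{record.risk_color.upper()}] {RISK_LEGEND[record.risk_color]}",
        f"trigger={record.trigger or 'none'}",
        f"t={record.timestamp:.2f}s",
    ]
    if record.survey is not None and record.survey.sat_pct is not None:
        parts.append(f"SAT={record.survey.sat_pct:.0f}% BPM={record.survey.bpm:.0f}")
    payload = asdict(record)
    return " | ".join(parts) + "\n" + json.dumps(payload, sort_keys=True)


def run_monitor(
    frames: Iterable[Frame],
    config: MonitorConfig,
    state: MonitorState | None = None,
) -> tuple[MonitorState, list[dict]]:
    """Replay a frame stream; deterministic event log."""
    state = state or MonitorState()
    log: list[dict] = []
    for frame in frames:
        state, events = monitor_step(frame, state, config)
        log.extend(events)
    return state, log
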