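"""Score a scripted maze session.

Drives the arm-access state machine with a known itinerary — the animal
visits baited arm 4, baited arm 2, never-baited arm 7, re-enters arm 4, then
empties arms 6 and 8 — and prints the cognitive summary: latency, working-
and reference-memory errors, path length, speed, dwell fractions and
stillness (S) spots."""

from ramtrack import behavior, build_geometry, metrics
from ramtrack.synthetic import scripted_path, session_waypoints
from ramtrack.tracker import TargetPos

geo = build_geometry()
baited = [2, 4, 6, 8]
wps, pauses = session_waypoints(geo, [4, 2, 7, 4, 6, 8], food_pause_s=3.0)
path = scripted_path(geo, wps, speeds_cm_s=12.0, fps=20.0, pauses_s=pauses)
points = [
    TargetPos(float(t), float(x), float(y), True, "single-outline")
    for t, (x, y) in zip(path.t, path.positions)
]

state = behavior.score_trajectory(points, geo, baited)
traj = metrics.Trajectory.from_points(points, geo.cm_per_px, 0.05)
report = metrics.build_report(traj, state, geo)

print(f"arm sequence       : {report.arm_sequence}")
print(f"latency            : {report.latency_s:.1f} s  (all baited arms emptied)")
print(f"working-memory err : {report.short_term_errors}  (re-entry into arm 4)")
print(f"reference-mem err  : {report.long_term_errors}  (first entry into never-baited arm 7)")
print(f"path length        : {report.path_length_m:.2f} m")
print(f"average speed      : {report.avg_speed_cm_s:.1f} cm/s")
print(f"dwell platform/baited/non-baited : "
      f"{report.pct_time_platform:.1f}% / {report.pct_time_baited_arms:.1f}% / "
      f"{report.pct_time_nonbaited_arms:.1f}%")
print(f"S spots            : {report.n_s_spots} episodes, "
      f"{report.s_spot_duration_s:.1f} s total stillness")
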