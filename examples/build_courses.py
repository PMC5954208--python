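"""Build walk-training courses: infant-derived and geometric baselines.

The infant-derived course samples a random 4-min block (walking plus stops,
stationary periods capped at 2 s) from each of 15 sessions and concatenates
them into a 1-h schedule of walk-to-waypoint and timed-stop elements. The
geometric baselines are a straight line, a fixed circle, and a square with
alternating stop patterns.
"""

from varietywalk import (
    CourseRecipe,
    PathGenParams,
    build_infant_course,
    circle_course,
    generate_session,
    line_course,
    square_course,
    write_course,
)

sessions = [generate_session(PathGenParams(seed=200 + i), f"walker{i}") for i in range(15)]
infant = build_infant_course(sessions, CourseRecipe(seed=1))
line, circle, square = line_course(), circle_course(), square_course()

for course in (infant, line, circle, square):
    walks, stops = course.walk_elements(), course.stop_elements()
    print(
        f"{course.course_id:15s} {course.total_duration():7.1f} s, "
        f"{len(walks):5d} walk targets, {len(stops):3d} stops "
        f"(longest stop {course.max_stop():.1f} s)"
    )

write_course(infant, "infant_course.json")
print()
print("infant course written to infant_course.json; total 3600 s = 15 walkers")
print("x 4 min each, no stop exceeding the 2 s stabilization cap.")
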