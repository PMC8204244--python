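activity,shortest_segment_mean_s,shortest_segment_sd_s,longest_segment_mean_s,longest_segment_sd_s,segment_count_mean,segment_count_sd,total_duration_mean_s,total_duration_sd_s,percent_clean,recording_duration_s
watching_a_video,13.1,13.5,78.1,42.4,9.3,3.6,264.6,24.9,88.2,300
reading,5.9,1.3,38.5,18.6,12.5,2.5,177.9,50.5,59.3,300
conversation,5.4,0.4,20.8,11.1,9.8,3.3,97.1,41.3,32.3,300
using_a_computer,5.4,0.6,18.5,11.2,9,3.9,89.1,56.1,29.7,300
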