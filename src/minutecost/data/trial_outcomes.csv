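arm,measure,week,mean_weekly_minutes,sd,n
intervention,par,0,8.0,15.0,104
intervention,par,26,112.8,97.1,87
intervention,par,52,108.6,107.2,87
control,par,0,8.5,14.6,101
control,par,26,63.5,88.7,85
control,par,52,75.9,89.8,85
intervention,accelerometer,0,35.8,69.7,104
intervention,accelerometer,26,75.8,91.0,87
intervention,accelerometer,52,70.4,86.4,87
control,accelerometer,0,28.7,48.2,101
control,accelerometer,26,43.0,60.9,85
control,accelerometer,52,55.5,74.6,85
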