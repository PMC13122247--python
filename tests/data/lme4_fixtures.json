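{"implicit_1":{"task":"implicit","seed":1,"terms":["Intercept","gaze_validity","body_head_congruency","gaze_validity:body_head_congruency"],"estimate":[1.1442685734,0.84357670281,0.97694405263,-1.033851885],"se":[0.11721544569,0.13711738603,0.14120613242,0.20655473006]},"implicit_2":{"task":"implicit","seed":2,"terms":["Intercept","gaze_validity","body_head_congruency","gaze_validity:body_head_congruency"],"estimate":[0.96771640153,1.2374960509,1.2568760398,-1.2837106826],"se":[0.10643674205,0.1472992641,0.14350362057,0.2181927132]},"implicit_3":{"task":"implicit","seed":3,"terms":["Intercept","gaze_validity","body_head_congruency","gaze_validity:body_head_congruency"],"estimate":[0.91931725908,1.1361284782,1.3325826237,-1.23044176],"se":[0.10845869213,0.13722524925,0.14728628764,0.21437987322]},"implicit_4":{"task":"implicit","seed":4,"terms":["Intercept","gaze_validity","body_head_congruency","gaze_validity:body_head_congruency"],"estimate":[0.95436904633,0.83354018216,0.76948900303,-0.69591183687],"se":[0.10094777612,0.13499081956,0.12812617546,0.19341684175]},"implicit_5":{"task":"implicit","seed":5,"terms":["Intercept","gaze_validity","body_head_congruency","gaze_validity:body_head_congruency"],"estimate":[1.1080695006,0.83451821218,0.86980895629,-1.0618307379],"se":[0.10702625046,0.13585266095,0.13700926775,0.2004912542]},"implicit_6":{"task":"implicit","seed":6,"terms":["Intercept","gaze_validity","body_head_congruency","gaze_validity:body_head_congruency"],"estimate":[0.91971248965,1.1503576604,1.0893944474,-1.4122315685],"se":[0.10629564995,0.13799142812,0.13603161461,0.20253212351]},"explicit_7":{"task":"explicit","seed":7,"terms":["Intercept","body_head_congruency"],"estimate":[1.7075425817,0.012332619498],"se":[0.077763079991,0.070091756577]},"explicit_8":{"task":"explicit","seed":8,"terms":["Intercept","body_head_congruency"],"estimate":[1.7348765559,-0.0455568882],"se":[0.078908748273,0.070514224654]},"explicit_9":{"task":"explicit","seed":9,"terms":["Intercept","body_head_congruency"],"estimate":[1.7012320879,-0.029200141508],"se":[0.071661302984,0.069657206638]},"explicit_10":{"task":"explicit","seed":10,"terms":["Intercept","body_head_congruency"],"estimate":[1.696142408,0.055474979318],"se":[0.07870319176,0.073052704329]},"lmm_implicit_1":{"task":"lmm","seed":1,"terms":["Intercept","correct","aq_score","correct:aq_score"],"estimate":[-1.3900609654,1.6661354241,0.012465470052,0.032408018284],"se":[0.047180515263,0.037958493206,0.046376825304,0.036667979711],"df":[160.5138191625,133.4563169333,141.6544965306,125.5213958987],"t":[-29.4626067055,43.8936133478,0.26878661854,0.88382339415]}}
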