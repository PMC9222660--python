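index,component,temp_C,day,mean,sd,n
hardness,radish,45,0,763.28,57.54,10
chewiness,radish,45,0,93.04,49.48,10
hardness,vegetable,45,0,277.87,78.42,10
chewiness,vegetable,45,0,66.15,21.45,10
hardness,radish,45,7,634.29,141.37,10
chewiness,radish,45,7,54.3,17.49,10
hardness,vegetable,45,7,194.18,71.49,10
chewiness,vegetable,45,7,59.19,19.93,10
hardness,radish,45,14,760.48,98.12,10
chewiness,radish,45,14,34.16,12.64,10
hardness,vegetable,45,14,228.13,79.5,10
chewiness,vegetable,45,14,54.17,19.57,10
hardness,radish,45,21,605.33,121.4,10
chewiness,radish,45,21,46.19,19.76,10
hardness,vegetable,45,21,200.42,77.8,10
chewiness,vegetable,45,21,43.02,18.63,10
hardness,radish,45,28,458.82,93.37,10
chewiness,radish,45,28,40.6,22.33,10
hardness,vegetable,45,28,152.87,26.93,10
chewiness,vegetable,45,28,41.82,16.66,10
hardness,radish,45,35,344.55,105.05,10
chewiness,radish,45,35,39.89,24.69,10
hardness,vegetable,45,35,69.9,25.88,10
chewiness,vegetable,45,35,28.17,10.95,10
hardness,radish,45,42,251.28,72.92,10
chewiness,radish,45,42,35.73,10.67,10
hardness,vegetable,45,42,98.89,38.48,10
chewiness,vegetable,45,42,34.92,13.64,10
hardness,radish,45,49,233.73,71.3,10
chewiness,radish,45,49,46.84,14.65,10
hardness,vegetable,45,49,68.27,30.23,10
chewiness,vegetable,45,49,23.58,12.61,10
hardness,radish,45,56,191.81,72.85,10
chewiness,radish,45,56,41.83,26.04,10
hardness,vegetable,45,56,79.13,35.95,10
chewiness,vegetable,45,56,28.39,13.87,10
hardness,radish,45,63,249.18,109.63,10
chewiness,radish,45,63,41.35,32.65,10
hardness,vegetable,45,63,65.08,29.63,10
chewiness,vegetable,45,63,20.48,8.3,10
hardness,radish,45,70,243.71,32.53,10
chewiness,radish,45,70,29.36,10.84,10
hardness,vegetable,45,70,64.18,22.86,10
chewiness,vegetable,45,70,18.99,9.25,10
hardness,radish,45,77,219.84,55.44,10
chewiness,radish,45,77,27.63,8.75,10
hardness,vegetable,45,77,58.17,15.18,10
chewiness,vegetable,45,77,20.47,5.45,10
hardness,radish,45,84,148.97,29.84,10
chewiness,radish,45,84,35.67,12.72,10
hardness,vegetable,45,84,69.12,18.84,10
chewiness,vegetable,45,84,15.45,7.84,10
hardness,radish,35,0,763.28,57.54,10
chewiness,radish,35,0,93.04,49.48,10
hardness,vegetable,35,0,277.87,78.42,10
chewiness,vegetable,35,0,66.15,21.45,10
hardness,radish,35,14,691.83,114.67,10
chewiness,radish,35,14,70.49,33.83,10
hardness,vegetable,35,14,259.48,16.05,10
chewiness,vegetable,35,14,82.72,25.6,10
hardness,radish,35,28,635.23,117.83,10
chewiness,radish,35,28,60.41,25.96,10
hardness,vegetable,35,28,192.59,49.61,10
chewiness,vegetable,35,28,52.98,15.82,10
hardness,radish,35,42,644.19,107.13,10
chewiness,radish,35,42,79.25,44.1,10
hardness,vegetable,35,42,177.5,53.4,10
chewiness,vegetable,35,42,48.95,16.51,10
hardness,radish,35,56,596.58,117.58,10
chewiness,radish,35,56,49.3,24.16,10
hardness,vegetable,35,56,165.28,45.77,10
chewiness,vegetable,35,56,49.94,13.54,10
hardness,radish,35,70,420.33,94.18,10
chewiness,radish,35,70,58.08,27.58,10
hardness,vegetable,35,70,108.13,61.94,10
chewiness,vegetable,35,70,33.63,14.52,10
hardness,radish,35,84,181.78,73.94,10
chewiness,radish,35,84,64.52,25.51,10
hardness,vegetable,35,84,80.38,27.95,10
chewiness,vegetable,35,84,30.45,10.7,10
hardness,radish,35,98,261.48,76.66,10
chewiness,radish,35,98,40.08,17.16,10
hardness,vegetable,35,98,86.08,29.92,10
chewiness,vegetable,35,98,26.07,8.3,10
hardness,radish,35,112,251.32,67.48,10
chewiness,radish,35,112,35.66,15.44,10
hardness,vegetable,35,112,109.68,23.22,10
chewiness,vegetable,35,112,35.67,9.12,10
hardness,radish,35,126,240.09,71.86,10
chewiness,radish,35,126,25.21,27.68,10
hardness,vegetable,35,126,59.91,19.58,10
chewiness,vegetable,35,126,18.73,6.77,10
hardness,radish,35,140,94.92,24.35,10
chewiness,radish,35,140,12.5,7.24,10
hardness,vegetable,35,140,64.28,22.22,10
chewiness,vegetable,35,140,18.37,7.76,10
hardness,radish,35,154,113.25,30.51,10
chewiness,radish,35,154,17.88,7.14,10
hardness,vegetable,35,154,67.01,15.92,10
chewiness,vegetable,35,154,20.2,8.01,10
hardness,radish,25,0,763.28,57.54,10
chewiness,radish,25,0,93.04,49.48,10
hardness,vegetable,25,0,277.87,78.42,10
chewiness,vegetable,25,0,66.15,21.45,10
hardness,radish,25,56,730.98,108.74,10
chewiness,radish,25,56,67.41,23.88,10
hardness,vegetable,25,56,273.82,29.94,10
chewiness,vegetable,25,56,58.75,14.36,10
hardness,radish,25,112,659.29,76.18,10
chewiness,radish,25,112,56.93,14.59,10
hardness,vegetable,25,112,189.99,40.19,10
chewiness,vegetable,25,112,65.87,18.52,10
hardness,radish,25,168,403.41,100.74,10
chewiness,radish,25,168,57.12,15.59,10
hardness,vegetable,25,168,216.67,45.01,10
chewiness,vegetable,25,168,46.69,15.85,10
hardness,radish,25,224,408.97,106.85,10
chewiness,radish,25,224,45.81,24.2,10
hardness,vegetable,25,224,221.66,59.5,10
chewiness,vegetable,25,224,44.39,15.51,10
hardness,radish,25,280,268.74,61.49,10
chewiness,radish,25,280,35.38,15.85,10
hardness,vegetable,25,280,135.88,37.52,10
chewiness,vegetable,25,280,40.22,19.91,10
hardness,radish,25,336,182.95,63.06,10
chewiness,radish,25,336,25.52,10.21,10
hardness,vegetable,25,336,76.22,32.39,10
chewiness,vegetable,25,336,27.12,11.08,10
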